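"""Domain types for feed-energy evaluation in growing pigs.

All energies are expressed per kg of dry matter (DM) throughout the
package; conversion from an as-fed basis happens only when raw files are
ingested.  Inclusion rates are stored as printed percentages of diet DM
and converted to fractions at computation time.

Symbols follow the field's convention: GE (gross energy), DE (digestible
energy), ME (metabolizable energy), IVDE (in vitro digestible energy),
GEI/GEO/GEU (daily GE intake / fecal output / urinary output, kcal/d),
DMI (dry-matter intake, kg/d).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


class InvalidRecordError(ValueError):
    """A record violates a domain invariant."""


class ImplausibleBalanceError(InvalidRecordError):
    """An energy-balance record implies negative digestion."""


@dataclass(frozen=True)
class IngredientComposition:
    """Chemical composition of one feed ingredient (% of DM except GE).

    Parameters
    ----------
    ingredient_id : str
        Short label, e.g. ``"corn"``.
    dm : float
        Dry matter, % of as-fed mass, in (0, 100].
    ge : float
        Gross energy, kcal/kg DM.
    cp, ee, ash, ndf, adf : float
        Crude protein, ether extract, ash, neutral- and acid-detergent
        fiber, % of DM.
    """

    ingredient_id: str
    dm: float
    ge: float
    cp: float = 0.0
    ee: float = 0.0
    ash: float = 0.0
    ndf: float = 0.0
    adf: float = 0.0

    def __post_init__(self) -> None:
        if not self.ge > 0:
            raise InvalidRecordError(f"{self.ingredient_id}: GE must be > 0")
        if not (0 < self.dm <= 100):
            raise InvalidRecordError(f"{self.ingredient_id}: DM must be in (0, 100]")
        for name in ("cp", "ee", "ash", "ndf", "adf"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise InvalidRecordError(
                    f"{self.ingredient_id}: {name}={v} outside [0, 100]"
                )


@dataclass(frozen=True)
class DietComponent:
    """One (ingredient, inclusion) entry of a diet formulation.

    ``energy_free`` marks mineral/vitamin supplements (dicalcium
    phosphate, limestone, salt, premix) that contribute zero energy to
    weighted sums.  ``is_test`` marks the single test ingredient of a
    substitution diet.
    """

    ingredient_id: str
    inclusion: float  # % of diet DM
    energy_free: bool = False
    is_test: bool = False

    def __post_init__(self) -> None:
        if self.inclusion < 0:
            raise InvalidRecordError(
                f"{self.ingredient_id}: inclusion {self.inclusion} < 0"
            )


@dataclass(frozen=True)
class DietFormulation:
    """Composition of one experimental or validation diet (% of diet DM)."""

    diet_id: str
    components: tuple[DietComponent, ...]
    analyzed_ge: Optional[float] = None  # GE_d, kcal/kg DM, from proximate analysis

    def __post_init__(self) -> None:
        total = sum(c.inclusion for c in self.components)
        if abs(total - 100.0) > 0.05:
            raise InvalidRecordError(
                f"diet {self.diet_id}: inclusions sum to {total:.2f}, not 100"
            )
        if sum(c.is_test for c in self.components) > 1:
            raise InvalidRecordError(
                f"diet {self.diet_id}: more than one test ingredient flagged"
            )

    @property
    def test_component(self) -> Optional[DietComponent]:
        for c in self.components:
            if c.is_test:
                return c
        return None

    def energetic_components(self) -> tuple[DietComponent, ...]:
        return tuple(c for c in self.components if not c.energy_free)


@dataclass(frozen=True)
class BalanceObservation:
    """One pig-period total-collection energy balance record.

    ``pseudo`` marks a record that is a published treatment mean rather
    than a raw pig observation (printed tables report per-diet means).
    """

    pig_id: str
    batch: int
    period: int
    diet_id: str
    dmi: float  # kg DM/d
    gei: float  # kcal/d
    geo: float  # kcal/d, fecal
    geu: float  # kcal/d, urinary
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.dmi > 0:
            raise InvalidRecordError(f"pig {self.pig_id}: DMI must be > 0")
        if not self.gei > 0:
            raise InvalidRecordError(f"pig {self.pig_id}: GEI must be > 0")
        if not (0 <= self.geo < self.gei):
            raise ImplausibleBalanceError(
                f"pig {self.pig_id}: fecal output {self.geo} not in [0, GEI={self.gei})"
            )
        if not (0 <= self.geu < self.gei - self.geo):
            raise ImplausibleBalanceError(
                f"pig {self.pig_id}: urinary output {self.geu} "
                f"not in [0, GEI-GEO={self.gei - self.geo})"
            )


@dataclass(frozen=True)
class DietEnergy:
    """Diet-level energy concentrations (kcal/kg DM) and coefficients.

    ``d_coef`` is the digestibility DE:GE and ``m_coef`` the
    metabolizability ME:GE of dietary energy.
    """

    diet_id: str
    ge_d: float
    de_d: float
    me_d: float
    d_coef: float
    m_coef: float
    n_obs: int = 1
    cv_de: Optional[float] = None  # %, 100·SD/mean over replicates
    cv_me: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.me_d <= self.de_d <= self.ge_d):
            raise InvalidRecordError(
                f"diet {self.diet_id}: require 0 < ME ({self.me_d}) <= DE "
                f"({self.de_d}) <= GE ({self.ge_d})"
            )
        for name in ("d_coef", "m_coef"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise InvalidRecordError(
                    f"diet {self.diet_id}: {name}={v} outside (0, 1]"
                )


@dataclass(frozen=True)
class InVitroRun:
    """One digestion-tube record of the simulated digestion assay.

    ``w_t`` — DM mass of sample in the tube (kg); ``ge_t`` — GE of the
    sample charged (kcal); ``ge_r`` — GE of the defatted dried residue
    (kcal); ``ge_e`` — GE of the enzyme-blank residue (kcal).
    """

    sample_id: str
    w_t: float
    ge_t: float
    ge_r: float
    ge_e: float
    batch: int = 1

    def __post_init__(self) -> None:
        if not self.w_t > 0:
            raise InvalidRecordError(f"{self.sample_id}: tube mass must be > 0")
        if not self.ge_t > 0:
            raise InvalidRecordError(f"{self.sample_id}: sample GE must be > 0")
        if self.ge_r < 0 or self.ge_e < 0:
            raise InvalidRecordError(f"{self.sample_id}: residue energies must be >= 0")


@dataclass(frozen=True)
class IngredientEnergy:
    """Ingredient-level energy values (kcal/kg DM) with provenance.

    ``method`` records whether DE/ME came from a near-sole-ingredient
    diet (direct) or by difference against the corn basal (substitution);
    ``p_ti`` is the test ingredient's share of dietary energy used by the
    substitution method.
    """

    ingredient_id: str
    de: Optional[float] = None
    me: Optional[float] = None
    ivde: Optional[float] = None
    method: Optional[str] = None  # "direct" | "substitution"
    p_ti: Optional[float] = None
    cv_de: Optional[float] = None
    cv_me: Optional[float] = None
    cv_ivde: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("de", "me", "ivde"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidRecordError(f"{self.ingredient_id}: {name}={v} < 0")
        if self.method == "substitution":
            if self.p_ti is None or not (0 < self.p_ti <= 1):
                raise InvalidRecordError(
                    f"{self.ingredient_id}: substitution requires p_ti in (0, 1], "
                    f"got {self.p_ti}"
                )


@dataclass(frozen=True)
class AdditivityResult:
    """Agreement of one mixed diet's determined vs calculated/predicted energy."""

    diet_id: str
    quantity: str  # "GE" | "IVDE" | "DE" | "ME"
    determined: float
    calculated: Optional[float] = None
    predicted: Optional[float] = None
    difference: Optional[float] = None  # determined − comparator
    sem: Optional[float] = None
    t_p_value: Optional[float] = None
    p_censored: bool = False  # True when the source prints "<0.001"

    VALID_QUANTITIES = ("GE", "IVDE", "DE", "ME")

    def __post_init__(self) -> None:
        if self.quantity not in self.VALID_QUANTITIES:
            raise InvalidRecordError(f"unknown quantity {self.quantity!r}")


def weighted_ge(
    formulation: DietFormulation,
    ingredients: dict[str, IngredientComposition],
) -> float:
    """Composition-weighted diet GE (kcal/kg DM), supplements at zero."""
    total = 0.0
    for c in formulation.energetic_components():
        if c.ingredient_id not in ingredients:
            raise KeyError(
                f"diet {formulation.diet_id}: no composition for {c.ingredient_id}"
            )
        total += c.inclusion / 100.0 * ingredients[c.ingredient_id].ge
    return total
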