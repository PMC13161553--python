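"""In vivo energy evaluation from total-collection balance records.

Diet-level digestible energy (DE) and metabolizable energy (ME) follow
the classic balance identities

    DE_d = (GEI - GEO) / DMI
    ME_d = (GEI - GEO - GEU) / DMI

with GEI/GEO/GEU the daily gross-energy intake and fecal/urinary outputs
(kcal/d) and DMI the dry-matter intake (kg/d).  Ingredient-level values
come either from a near-sole-ingredient diet (direct method) or, for
ingredients that cannot be fed alone, by difference against a corn basal
diet (substitution method):

    D_ti = D_cd + (D_td - D_cd) / P_ti,      DE_ti = GE_ti * D_ti

where D are energy digestibility (DE:GE) or metabolizability (ME:GE)
coefficients of the test ingredient, corn basal diet and test diet, and
P_ti is the share of dietary energy contributed by the test ingredient.
"""

from __future__ import annotations

import logging
import math
import warnings
from statistics import mean, stdev
from typing import Iterable, Optional, Sequence

from .types import (
    BalanceObservation,
    DietEnergy,
    DietFormulation,
    IngredientComposition,
    IngredientEnergy,
    InvalidRecordError,
)

logger = logging.getLogger(__name__)

#: minimum test-ingredient inclusion (% of diet DM) for the direct method
DIRECT_METHOD_MIN_INCLUSION = 90.0


class WrongMethodError(ValueError):
    """Diet composition does not support the requested evaluation method."""


class MissingDietError(KeyError):
    """No observations available for the requested diet."""


def diet_energy(obs: BalanceObservation) -> DietEnergy:
    """Diet DE/ME concentrations (kcal/kg DM) from one balance record."""
    de_d = (obs.gei - obs.geo) / obs.dmi
    me_d = (obs.gei - obs.geo - obs.geu) / obs.dmi
    ge_d = obs.gei / obs.dmi
    return DietEnergy(
        diet_id=obs.diet_id,
        ge_d=ge_d,
        de_d=de_d,
        me_d=me_d,
        d_coef=de_d / ge_d,
        m_coef=me_d / ge_d,
        n_obs=1,
    )


def aggregate_diet_energy(
    observations: Iterable[BalanceObservation],
    diet_id: str,
    screen_outliers: bool = False,
) -> DietEnergy:
    """Treatment-mean diet energy over replicate pigs.

    Per-observation energies are computed first, then averaged;
    coefficients are ratios of the mean concentrations.  CVs are sample
    CVs (100*SD/mean, ddof=1).  With ``screen_outliers`` the DE values
    are IQR-screened and flagged observations dropped before averaging.
    """
    obs = [o for o in observations if o.diet_id == diet_id]
    if not obs:
        raise MissingDietError(f"no observations for diet {diet_id}")
    energies = [diet_energy(o) for o in obs]
    if screen_outliers and len(energies) >= 4:
        kept_idx, flagged_idx = iqr_screen([e.de_d for e in energies], indices=True)
        for i in flagged_idx:
            logger.warning(
                "diet %s: observation %s flagged as DE outlier (%.1f kcal/kg)",
                diet_id, obs[i].pig_id, energies[i].de_d,
            )
        energies = [energies[i] for i in kept_idx]
    de_vals = [e.de_d for e in energies]
    me_vals = [e.me_d for e in energies]
    ge_vals = [e.ge_d for e in energies]
    n = len(energies)
    de_m, me_m, ge_m = mean(de_vals), mean(me_vals), mean(ge_vals)
    cv_de = 100.0 * stdev(de_vals) / de_m if n > 1 else None
    cv_me = 100.0 * stdev(me_vals) / me_m if n > 1 else None
    return DietEnergy(
        diet_id=diet_id,
        ge_d=ge_m,
        de_d=de_m,
        me_d=me_m,
        d_coef=de_m / ge_m,
        m_coef=me_m / ge_m,
        n_obs=n,
        cv_de=cv_de,
        cv_me=cv_me,
    )


def direct_ingredient_energy(
    diet: DietEnergy,
    formulation: DietFormulation,
    ingredient: IngredientComposition,
) -> IngredientEnergy:
    """Ingredient DE/ME by the direct method (near-sole-ingredient diet).

    Scales the diet's digestibility and metabolizability coefficients to
    the ingredient's own GE: ``DE_ti = GE_ti * DE_d / GE_d``.
    """
    comp = _find_component(formulation, ingredient.ingredient_id)
    if comp.inclusion < DIRECT_METHOD_MIN_INCLUSION:
        raise WrongMethodError(
            f"{ingredient.ingredient_id} included at {comp.inclusion}% "
            f"(< {DIRECT_METHOD_MIN_INCLUSION}%) in diet {formulation.diet_id}; "
            "use substitution_ingredient_energy"
        )
    return IngredientEnergy(
        ingredient_id=ingredient.ingredient_id,
        de=ingredient.ge * diet.d_coef,
        me=ingredient.ge * diet.m_coef,
        method="direct",
        cv_de=diet.cv_de,
        cv_me=diet.cv_me,
    )


def substitution_ingredient_energy(
    basal: DietEnergy,
    test: DietEnergy,
    formulation: DietFormulation,
    ingredient: IngredientComposition,
) -> IngredientEnergy:
    """Ingredient DE/ME by the substitution (difference) method.

    ``P_ti``, the test ingredient's share of dietary energy, uses the
    analyzed test-diet GE when the formulation carries one, falling back
    to the measured ``test.ge_d``.
    """
    if basal is None:
        raise ValueError("substitution method requires a basal diet energy")
    comp = formulation.test_component
    if comp is None:
        comp = _find_component(formulation, ingredient.ingredient_id)
    x_ti = comp.inclusion
    ge_d_test = formulation.analyzed_ge if formulation.analyzed_ge else test.ge_d
    p_ti = (x_ti / 100.0) * ingredient.ge / ge_d_test
    if not (0 < p_ti <= 1):
        raise InvalidRecordError(
            f"{ingredient.ingredient_id}: energy proportion P_ti={p_ti:.3f} "
            "outside (0, 1]"
        )
    d_ti = basal.d_coef + (test.d_coef - basal.d_coef) / p_ti
    m_ti = basal.m_coef + (test.m_coef - basal.m_coef) / p_ti
    return IngredientEnergy(
        ingredient_id=ingredient.ingredient_id,
        de=ingredient.ge * d_ti,
        me=ingredient.ge * m_ti,
        method="substitution",
        p_ti=p_ti,
        cv_de=test.cv_de,
        cv_me=test.cv_me,
    )


def iqr_screen(
    values: Sequence[float],
    k: float = 1.5,
    indices: bool = False,
) -> tuple[list, list]:
    """Tukey fence outlier screen.

    Values outside [Q1 - k*IQR, Q3 + k*IQR] are flagged.  Quartiles are
    Tukey hinges (median-inclusive): the sorted sample is split at the
    median, which belongs to both halves when n is odd, and Q1/Q3 are
    the medians of the halves.  With fewer than 4 values the screen is
    skipped with a warning and everything is kept.

    Returns ``(kept, flagged)`` as values, or index lists when
    ``indices`` is true.
    """
    vals = list(values)
    n = len(vals)
    if n < 4:
        warnings.warn(f"IQR screen skipped: only {n} values (need >= 4)")
        return (list(range(n)), []) if indices else (vals, [])
    # Tukey hinges are median-INCLUSIVE: for odd n the median belongs to
    # both halves.  (The median-exclusive variant would leave e.g.
    # {1,2,3,4,100} unflagged because Q3 jumps to 52.)
    q1, q3 = _tukey_hinges(sorted(vals))
    lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
    kept, flagged = [], []
    for i, v in enumerate(vals):
        (kept if lo <= v <= hi else flagged).append(i)
    if indices:
        return kept, flagged
    return [vals[i] for i in kept], [vals[i] for i in flagged]


def _tukey_hinges(s: Sequence[float]) -> tuple[float, float]:
    n = len(s)
    half = (n + 1) // 2  # median included in both halves when n is odd
    return _median(s[:half]), _median(s[n - half :])


def _median(s: Sequence[float]) -> float:
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def _find_component(formulation: DietFormulation, ingredient_id: str):
    for c in formulation.components:
        if c.ingredient_id == ingredient_id:
            return c
    raise KeyError(
        f"{ingredient_id} is not a component of diet {formulation.diet_id}"
    )


def reconstruct_test_diet_coefficient(
    basal_coef: float, ingredient_coef: float, p_ti: float
) -> float:
    """Algebraic inverse of the substitution identity.

    Recovers the test-diet coefficient from basal and ingredient
    coefficients: ``D_td = D_cd + (D_ti - D_cd) * P_ti``.
    """
    return basal_coef + (ingredient_coef - basal_coef) * p_ti
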