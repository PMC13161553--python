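"""Synthetic feed-energy studies with the structure the analysis assumes.

Generates a complete study — an ingredient panel with known ("true")
energy values, near-sole-ingredient and corn-basal substitution diets,
a two-batch x three-period Youden-square balance trial, and replicated
in vitro digestion tubes — so that every pipeline stage can be exercised
and checked against generator truth.

The generator emulates the study conditions of the energy bioassay it
supports: 20 ingredients in three classes (cereal grains, protein feeds,
brans), six replicate pigs per diet (2 batches x 3 periods), feed intake
at 4% of a ~37 kg initial body weight, in vivo replicate CVs of roughly
0.7-6.5% and in vitro replicate CVs of roughly 0.1-1.4%, and an
approximately linear IVDE-DE relationship with class-level offsets
(near zero for cereals, negative for protein meals whose hindgut
fermentation the in vitro assay under-captures).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .types import (
    BalanceObservation,
    DietComponent,
    DietFormulation,
    IngredientComposition,
    InVitroRun,
)

_SUPPLEMENTS = (
    ("dicalcium_phosphate", 1.20),
    ("limestone", 1.00),
    ("salt", 0.46),
    ("premix", 0.14),
)
_SUPPLEMENT_TOTAL = sum(x for _, x in _SUPPLEMENTS)  # 2.80% of diet DM

# per-stage rng streams so each simulate_* call is independently seeded
_STREAM_INGREDIENTS, _STREAM_BALANCE, _STREAM_INVITRO = 11, 22, 33


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ClassPrior:
    """Generating ranges for one ingredient class."""

    ge_range: tuple[float, float]  # kcal/kg DM
    digestibility_range: tuple[float, float]  # DE:GE
    ivde_offset: float  # additive bias of IVDE vs the global line, kcal/kg
    cp_range: tuple[float, float]
    ndf_range: tuple[float, float]


DEFAULT_CLASS_PRIORS: dict[str, ClassPrior] = {
    "cereal": ClassPrior((4300.0, 4500.0), (0.86, 0.94), 0.0, (9.0, 15.0), (4.0, 20.0)),
    "protein": ClassPrior((4550.0, 5750.0), (0.58, 0.95), -280.0, (20.0, 72.0), (10.0, 66.0)),
    "bran": ClassPrior((4100.0, 5100.0), (0.55, 0.82), -120.0, (14.0, 19.0), (14.0, 42.0)),
}

DEFAULT_CLASS_COUNTS = {"cereal": 6, "protein": 11, "bran": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic energy bioassay.

    The defaults reproduce the design of the motivating study: 20
    ingredients, a 2-batch x 3-period Youden square with one pig per
    diet per batch-period (6 replicates/diet), feed intake at 4.0% of
    initial BW, in vivo noise calibrated to DE CVs of 0.7-6.5% and in
    vitro noise to replicate CVs of 0.1-1.4%, and a true calibration
    line IVDE = DE - 180 plus class offsets (the observed fit
    DE = 1.001*IVDE + 180 inverted).
    """

    seed: int = 0
    n_ingredients: int = 20
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    class_priors: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PRIORS))
    calib_slope: float = 1.0  # true IVDE = slope*DE + intercept + class offset
    calib_intercept: float = -180.0
    ivde_jitter_sd: float = 100.0  # ingredient-level scatter around the line, kcal/kg
    me_de_ratio_range: tuple[float, float] = (0.90, 0.98)
    invivo_cv_range: tuple[float, float] = (0.7, 6.5)  # % on ingredient DE
    urinary_cv: float = 10.0  # % relative noise on urinary output
    invitro_cv_range: tuple[float, float] = (0.1, 1.4)  # % on replicate IVDE
    n_batches: int = 2
    n_periods: int = 3
    dmi_fraction: float = 0.04  # feed intake as fraction of initial BW
    initial_bw: float = 37.3  # kg
    bw_sd: float = 4.7  # kg, between-pig spread
    diet_dm_fraction: float = 0.885  # DM content of mixed diets, as-fed
    n_invitro_reps: int = 5
    blank_ge: float = 0.20  # kcal, enzyme-blank residue per tube
    test_inclusion: float = 25.0  # % of diet DM for substitution diets
    cereal_inclusion: float = 97.2  # % of diet DM for direct-method diets

    @property
    def reps_per_diet(self) -> int:
        return self.n_batches * self.n_periods

    def validate(self) -> None:
        if sum(self.class_counts.values()) != self.n_ingredients:
            raise SimulationConfigError(
                f"class counts {self.class_counts} do not sum to "
                f"n_ingredients={self.n_ingredients}"
            )
        for rng_pair in (self.invivo_cv_range, self.invitro_cv_range):
            if rng_pair[0] < 0 or rng_pair[1] < rng_pair[0]:
                raise SimulationConfigError(f"bad CV range {rng_pair}")
        for cls in self.class_counts:
            if cls not in self.class_priors:
                raise SimulationConfigError(f"no prior for class {cls!r}")
            p = self.class_priors[cls]
            if p.ge_range[0] >= p.ge_range[1] or p.digestibility_range[0] >= p.digestibility_range[1]:
                raise SimulationConfigError(f"degenerate prior for class {cls!r}")


@dataclass(frozen=True)
class TrueIngredient:
    """An ingredient with its generating (true) energy values."""

    composition: IngredientComposition
    ingredient_class: str
    de: float
    me: float
    ivde: float

    @property
    def ingredient_id(self) -> str:
        return self.composition.ingredient_id

    @property
    def ge(self) -> float:
        return self.composition.ge


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _lognormal_factor(rng: np.random.Generator, cv_percent: float) -> float:
    """Mean-one multiplicative log-normal noise at the given CV (%)."""
    if cv_percent <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log(1 + (cv_percent / 100.0) ** 2)))
    return float(np.exp(rng.normal(0.0, sigma) - sigma**2 / 2))


def simulate_ingredients(config: SimulationConfig) -> list[TrueIngredient]:
    """Draw an ingredient panel with true DE/ME/IVDE values.

    True DE = digestibility x GE with the digestibility drawn from the
    class prior; ME/DE is uniform in ``me_de_ratio_range``; true IVDE
    follows the configured line plus the class offset and an
    ingredient-level jitter.
    """
    config.validate()
    rng = _rng(config, _STREAM_INGREDIENTS)
    out: list[TrueIngredient] = []
    idx = 0
    for cls in sorted(config.class_counts):
        prior: ClassPrior = config.class_priors[cls]
        for _ in range(config.class_counts[cls]):
            idx += 1
            ge = float(rng.uniform(*prior.ge_range))
            d = float(rng.uniform(*prior.digestibility_range))
            de = d * ge
            me = de * float(rng.uniform(*config.me_de_ratio_range))
            ivde = (
                config.calib_slope * de
                + config.calib_intercept
                + prior.ivde_offset
                + (rng.normal(0.0, config.ivde_jitter_sd) if config.ivde_jitter_sd > 0 else 0.0)
            )
            ivde = float(np.clip(ivde, 100.0, ge))
            comp = IngredientComposition(
                ingredient_id=f"{cls}_{idx:02d}",
                dm=float(rng.uniform(87.0, 93.0)),
                ge=ge,
                cp=float(rng.uniform(*prior.cp_range)),
                ee=float(rng.uniform(0.6, 8.0)),
                ash=float(rng.uniform(1.3, 9.8)),
                ndf=float(rng.uniform(*prior.ndf_range)),
                adf=float(rng.uniform(0.7, 20.0)),
            )
            out.append(TrueIngredient(comp, cls, de=de, me=me, ivde=ivde))
    return out


def study_formulations(
    ingredients: Sequence[TrueIngredient],
    config: SimulationConfig,
) -> list[DietFormulation]:
    """Direct diets for cereals, corn-basal substitution diets otherwise.

    The first cereal plays the role of the corn basal.  Diet ids are
    ``d01`` ... in panel order; the basal grain's own diet (d01) is the
    reference for the substitution method.
    """
    cereals = [i for i in ingredients if i.ingredient_class == "cereal"]
    if not cereals:
        raise SimulationConfigError("panel needs at least one cereal as basal grain")
    basal = cereals[0]
    ge_by_id = {i.ingredient_id: i.ge for i in ingredients}
    forms = []
    for k, ing in enumerate(ingredients, start=1):
        if ing.ingredient_class == "cereal":
            comps = [
                DietComponent(ing.ingredient_id, config.cereal_inclusion, is_test=True)
            ]
            filler = 100.0 - config.cereal_inclusion - _SUPPLEMENT_TOTAL
        else:
            comps = [
                DietComponent(basal.ingredient_id,
                              100.0 - config.test_inclusion - _SUPPLEMENT_TOTAL),
                DietComponent(ing.ingredient_id, config.test_inclusion, is_test=True),
            ]
            filler = 0.0
        for name, inc in _SUPPLEMENTS:
            comps.append(DietComponent(name, inc, energy_free=True))
        if filler > 1e-9:
            comps[0] = replace(comps[0], inclusion=comps[0].inclusion + filler)
        ge_d = sum(
            c.inclusion / 100.0 * ge_by_id[c.ingredient_id]
            for c in comps
            if not c.energy_free
        )
        forms.append(
            DietFormulation(diet_id=f"d{k:02d}", components=tuple(comps), analyzed_ge=ge_d)
        )
    return forms


def true_diet_coefficients(
    formulation: DietFormulation, ingredients: Sequence[TrueIngredient]
) -> tuple[float, float, float]:
    """(GE_d, digestibility, metabolizability) of a diet under exact additivity."""
    by_id = {i.ingredient_id: i for i in ingredients}
    ge_d = de_d = me_d = 0.0
    for c in formulation.energetic_components():
        ing = by_id[c.ingredient_id]
        f = c.inclusion / 100.0
        ge_d += f * ing.ge
        de_d += f * ing.de
        me_d += f * ing.me
    return ge_d, de_d / ge_d, me_d / ge_d


def simulate_balance_study(
    config: SimulationConfig,
    ingredients: Sequence[TrueIngredient],
    formulations: Sequence[DietFormulation],
) -> list[BalanceObservation]:
    """Youden-square balance trial with multiplicative log-normal noise.

    Each batch holds one pig per diet; in period t pig p receives diet
    (p + t) mod n, so every diet appears exactly once per batch-period
    and no pig repeats a diet.  Fecal output noise is calibrated so the
    replicate CV of the *ingredient-level* DE recovered downstream
    matches a per-diet target drawn from ``invivo_cv_range`` (diet-level
    noise is shrunk by the substitution amplification factor); urinary
    output carries ``urinary_cv`` relative noise.  Truncation guards
    keep every record within the balance invariants.
    """
    config.validate()
    n = len(formulations)
    if n < config.n_periods:
        raise SimulationConfigError(
            f"infeasible layout: {n} diets < {config.n_periods} periods"
        )
    rng = _rng(config, _STREAM_BALANCE)
    truth = {f.diet_id: true_diet_coefficients(f, ingredients) for f in formulations}
    by_id = {i.ingredient_id: i for i in ingredients}
    # Per-diet DE CV target. invivo_cv_range describes ingredient-level
    # replicate CVs (what energy panels report); the substitution method
    # amplifies diet-level noise by 1/P_ti, so substitution diets get a
    # correspondingly smaller diet-level target:
    #   CV(DE_ti) = CV(DE_td) * DE_td / (x_ti * DE_ti)
    lo, hi = config.invivo_cv_range
    target_cv: dict[str, float] = {}
    for f in formulations:
        cv_ing = float(rng.uniform(lo, hi))
        comp = f.test_component
        if comp is None or comp.inclusion >= 90.0:
            target_cv[f.diet_id] = cv_ing
        else:
            ge_d, d_d, _ = truth[f.diet_id]
            ing = by_id[comp.ingredient_id]
            de_td = d_d * ge_d
            target_cv[f.diet_id] = cv_ing * (comp.inclusion / 100.0) * ing.de / de_td
    obs: list[BalanceObservation] = []
    for batch in range(1, config.n_batches + 1):
        bw = np.clip(
            rng.normal(config.initial_bw, config.bw_sd, size=n), 25.0, 55.0
        )
        for period in range(1, config.n_periods + 1):
            for pig in range(n):
                form = formulations[(pig + period - 1) % n]
                ge_d, d_d, m_d = truth[form.diet_id]
                dmi = float(config.dmi_fraction * bw[pig] * config.diet_dm_fraction)
                gei = dmi * ge_d
                geo_true = gei * (1.0 - d_d)
                geu_true = gei * (d_d - m_d)
                # map the target DE CV onto fecal-output noise:
                # sd(DE)/DE = (GEO / (GEI-GEO)) * cv(GEO)
                cv_geo = target_cv[form.diet_id] * d_d / max(1.0 - d_d, 1e-9)
                geo = geo_true * _lognormal_factor(rng, cv_geo)
                geu = geu_true * _lognormal_factor(rng, config.urinary_cv)
                geo = min(geo, 0.95 * gei)
                geu = min(geu, 0.95 * (gei - geo))
                obs.append(
                    BalanceObservation(
                        pig_id=f"b{batch}p{pig + 1:02d}",
                        batch=batch,
                        period=period,
                        diet_id=form.diet_id,
                        dmi=dmi,
                        gei=gei,
                        geo=geo,
                        geu=geu,
                    )
                )
    return obs


def simulate_invitro_runs(
    config: SimulationConfig,
    ingredients: Sequence[TrueIngredient],
) -> list[InVitroRun]:
    """Replicated digestion tubes consistent with each true IVDE.

    Tubes charge 2 g DM for cereals and 1 g for other ingredients; the
    residue energy is back-computed from the true IVDE plus replicate
    noise at a per-sample CV drawn from ``invitro_cv_range``, so the
    forward computation recovers the noisy IVDE exactly and doubling the
    blank energy leaves IVDE unchanged by construction.
    """
    config.validate()
    rng = _rng(config, _STREAM_INVITRO)
    lo, hi = config.invitro_cv_range
    runs: list[InVitroRun] = []
    for ing in ingredients:
        w_t = 0.002 if ing.ingredient_class == "cereal" else 0.001
        cv = float(rng.uniform(lo, hi))
        ge_t = w_t * ing.ge
        for _ in range(config.n_invitro_reps):
            ivde_rep = ing.ivde * _lognormal_factor(rng, cv)
            ge_r = max(ge_t + config.blank_ge - ivde_rep * w_t, 0.0)
            runs.append(
                InVitroRun(
                    sample_id=ing.ingredient_id,
                    w_t=w_t,
                    ge_t=ge_t,
                    ge_r=ge_r,
                    ge_e=config.blank_ge,
                    batch=1,
                )
            )
    return runs


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete simulated study plus its generating truth."""

    config: SimulationConfig
    ingredients: list[TrueIngredient]
    formulations: list[DietFormulation]
    observations: list[BalanceObservation]
    invitro_runs: list[InVitroRun]

    @property
    def basal_diet_id(self) -> str:
        return self.formulations[0].diet_id

    def compositions(self) -> dict[str, IngredientComposition]:
        return {i.ingredient_id: i.composition for i in self.ingredients}


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate ingredients, diets, balance records and in vitro tubes."""
    ingredients = simulate_ingredients(config)
    # put the basal cereal first so formulations[0] is the basal diet
    ingredients.sort(key=lambda i: (i.ingredient_class != "cereal", i.ingredient_id))
    formulations = study_formulations(ingredients, config)
    observations = simulate_balance_study(config, ingredients, formulations)
    runs = simulate_invitro_runs(config, ingredients)
    return SyntheticStudy(config, ingredients, formulations, observations, runs)
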