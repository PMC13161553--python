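"""Additivity and agreement validation of energy values in mixed diets.

Feed formulation assumes energy additivity: a mixed diet's energy equals
the DM-inclusion-weighted sum of its ingredients' energies, with mineral
and vitamin supplements contributing zero.  This module computes such
calculated (from determined ingredient values) and predicted (from
calibration-predicted ingredient values) diet energies and quantifies
agreement with the in vivo determined values through per-diet one-sample
t-tests, the average relative difference (ARD)

    ARD = 100 * sqrt( sum_i (determined_i - predicted_i)^2 / n )
              / mean(determined)

and agreement regressions whose slope and intercept are tested against
1 and 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .calibration import LinearCalibration, fit_calibration
from .types import DietFormulation


class MissingIngredientValueError(KeyError):
    """A diet component lacks the ingredient-level value needed for the sum."""


def calculated_diet_energy(
    formulation: DietFormulation,
    ingredient_values: Mapping[str, float],
    quantity: str = "DE",
) -> float:
    """DM-inclusion-weighted sum of ingredient energies (kcal/kg DM).

    Energy-free supplements contribute zero; every other component must
    have a value in ``ingredient_values``.
    """
    missing = [
        c.ingredient_id
        for c in formulation.energetic_components()
        if c.ingredient_id not in ingredient_values
    ]
    if missing:
        raise MissingIngredientValueError(
            f"diet {formulation.diet_id}: no {quantity} value for {', '.join(missing)}"
        )
    return sum(
        c.inclusion / 100.0 * ingredient_values[c.ingredient_id]
        for c in formulation.energetic_components()
    )


def predicted_diet_energy(
    formulation: DietFormulation,
    calibration: LinearCalibration,
    ingredient_ivde: Mapping[str, float],
) -> float:
    """Diet energy from calibration-predicted ingredient values.

    Each energetic ingredient's IVDE is pushed through the calibration,
    then the predictions are combined by the same DM-inclusion-weighted
    sum as :func:`calculated_diet_energy`.
    """
    predicted = {
        ing: float(calibration.predict([x])[0]) for ing, x in ingredient_ivde.items()
    }
    return calculated_diet_energy(formulation, predicted, quantity=calibration.response)


def ard(determined: Sequence[float], predicted: Sequence[float]) -> float:
    """Average relative difference (%) between determined and predicted.

    Root-mean-square of the paired differences, relative to the mean of
    the determined values.  Scale-invariant and zero iff the vectors are
    equal.
    """
    d = np.asarray(determined, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if d.shape != p.shape or d.size < 1:
        raise ValueError("determined and predicted must be equal-length, n >= 1")
    m = d.mean()
    if m <= 0:
        raise ValueError("ARD undefined: mean of determined values is <= 0")
    return float(100.0 * np.sqrt(np.mean((d - p) ** 2)) / m)


def one_sample_t(
    determined_reps: Sequence[float], reference: float
) -> tuple[float, float, float]:
    """One-sample t-test of replicate determinations against a reference.

    Returns ``(mean_diff, sem, p)`` with df = n - 1.  With zero
    replicate variance and a non-zero difference the p-value is reported
    as the machine floor with a warning.
    """
    reps = np.asarray(determined_reps, dtype=float)
    if reps.size < 2:
        raise ValueError("one-sample t-test needs >= 2 replicates")
    mean_diff = float(reps.mean() - reference)
    sd = float(reps.std(ddof=1))
    sem = sd / np.sqrt(reps.size)
    if sd == 0:
        if mean_diff == 0:
            return 0.0, 0.0, 1.0
        import warnings

        warnings.warn("zero replicate variance with non-zero difference")
        return mean_diff, 0.0, float(np.finfo(float).tiny)
    t = mean_diff / sem
    p = 2 * stats.t.sf(abs(t), reps.size - 1)
    return mean_diff, float(sem), float(p)


def t_from_summary(mean_diff: float, sem: float, n: int) -> tuple[float, float]:
    """t statistic and two-sided p from a printed difference, SEM and n."""
    t = mean_diff / sem
    return float(t), float(2 * stats.t.sf(abs(t), n - 1))


@dataclass(frozen=True)
class AgreementVerdict:
    """Agreement regression of a comparator on determined values."""

    model: LinearCalibration
    p_slope: float  # H0: slope = 1
    p_intercept: float  # H0: intercept = 0
    verdict: str  # "additive" | "non-additive"


def agreement_regression(
    determined: Sequence[float],
    comparator: Sequence[float],
    label: str = "agreement",
    alpha: float = 0.05,
) -> AgreementVerdict:
    """Regress calculated/predicted values on determined values.

    The verdict is "additive" when neither the slope-vs-1 nor the
    intercept-vs-0 test is significant at ``alpha``.
    """
    model = fit_calibration(list(zip(determined, comparator)), response=label)
    p_slope, p_intercept = model.test_coefficients(slope0=1.0, intercept0=0.0)
    verdict = "additive" if (p_slope > alpha and p_intercept > alpha) else "non-additive"
    return AgreementVerdict(model=model, p_slope=p_slope, p_intercept=p_intercept, verdict=verdict)
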