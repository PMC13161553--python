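"""Linear calibration of in vivo energy values on in vitro digestible energy.

The core statistical object is a simple-linear-regression calibration
``y = slope * IVDE + intercept`` fitted by ordinary least squares, where
y is the in vivo digestible (DE) or metabolizable (ME) energy of an
ingredient, kcal/kg DM.  Predictions for new ingredients carry 95%
confidence intervals for the *mean response*

    yhat +/- t(1-a/2, n-2) * RSD * sqrt(1/n + (x0 - xbar)^2 / Sxx)

with RSD the residual standard deviation sqrt(SSE/(n-2)).  Slope and
intercept can be tested against reference values (1 and 0 for agreement
with the identity line), and two calibrations can be compared through a
pooled dummy-variable regression with interaction.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class DegenerateFitError(ValueError):
    """The predictor does not support a two-parameter linear fit."""


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a single predictor, got shape {x.shape}")
    return x


class LinearCalibration(RegressorMixin, BaseEstimator):
    """OLS calibration of an in vivo energy response on IVDE.

    Parameters
    ----------
    response : str
        Label of the response being calibrated, ``"DE"`` or ``"ME"``.
        Purely descriptive; it tags reports and errors.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted coefficients (kcal/kcal and kcal/kg DM).
    r2_ : float
        Coefficient of determination, 1 - SSE/SST.
    rsd_ : float
        Residual standard deviation, sqrt(SSE/(n-2)), kcal/kg DM.
    n_, df_resid_ : int
        Number of pairs and residual degrees of freedom (n - 2).
    x_mean_, s_xx_ : float
        Predictor mean and corrected sum of squares (leverage terms).
    se_slope_, se_intercept_ : float
        OLS standard errors of the coefficients.
    """

    def __init__(self, response: str = "DE"):
        self.response = response

    def fit(self, X, y):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("X and y lengths differ")
        n = x.size
        if n < 3:
            raise DegenerateFitError(
                f"{self.response} calibration needs n >= 3 pairs "
                f"(got {n}; with n = 2 the residual df is 0)"
            )
        if np.ptp(x) == 0:
            raise DegenerateFitError("constant predictor: slope is unidentifiable")
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept_, self.slope_ = ols.params
        self.se_intercept_, self.se_slope_ = ols.bse
        self.n_ = int(n)
        self.df_resid_ = int(n - 2)
        self.r2_ = float(ols.rsquared)
        self.rsd_ = float(np.sqrt(ols.ssr / self.df_resid_))
        self.x_mean_ = float(x.mean())
        self.s_xx_ = float(((x - self.x_mean_) ** 2).sum())
        self.coef_ = np.array([self.slope_])
        self.x_train_ = x.copy()
        self.y_train_ = y.copy()
        self._ols_ = ols
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * _as_1d(X)

    def predict_ci(self, X, level: float = 0.95):
        """Point prediction with mean-response confidence interval.

        Returns ``(yhat, lower, upper)`` arrays.  This is the interval
        for the conditional mean at x0, not a prediction interval for a
        new single observation.
        """
        check_is_fitted(self, "slope_")
        if self.df_resid_ < 1:
            raise DegenerateFitError("no residual degrees of freedom for intervals")
        x = _as_1d(X)
        yhat = self.intercept_ + self.slope_ * x
        tcrit = stats.t.ppf(1 - (1 - level) / 2, self.df_resid_)
        half = tcrit * self.rsd_ * np.sqrt(1 / self.n_ + (x - self.x_mean_) ** 2 / self.s_xx_)
        return yhat, yhat - half, yhat + half

    def test_coefficients(
        self, slope0: float = 1.0, intercept0: float = 0.0
    ) -> tuple[float, float]:
        """Two-sided t-tests of slope vs ``slope0`` and intercept vs ``intercept0``.

        Returns ``(p_slope, p_intercept)`` with df = n - 2.
        """
        check_is_fitted(self, "slope_")
        # an (almost) exact fit leaves only rounding noise in the SEs; a
        # t-ratio of two machine epsilons is meaningless
        exact = self.rsd_ <= 1e-8 * max(1.0, float(np.abs(self.y_train_).max()))
        scale = max(1.0, abs(self.slope_), abs(self.intercept_))

        def _p(diff: float, se: float) -> float:
            if exact or se == 0:
                return 1.0 if abs(diff) < 1e-8 * scale else 0.0
            return float(2 * stats.t.sf(abs(diff / se), self.df_resid_))

        return (
            _p(self.slope_ - slope0, self.se_slope_),
            _p(self.intercept_ - intercept0, self.se_intercept_),
        )

    def summary(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "response": self.response,
            "slope": self.slope_,
            "intercept": self.intercept_,
            "n": self.n_,
            "r2": self.r2_,
            "rsd": self.rsd_,
            "x_mean": self.x_mean_,
            "s_xx": self.s_xx_,
            "df_resid": self.df_resid_,
        }


def fit_calibration(
    pairs: Sequence[tuple[float, float]], response: str = "DE"
) -> LinearCalibration:
    """Fit a calibration from ``(ivde, y)`` pairs."""
    arr = np.asarray(pairs, dtype=float)
    return LinearCalibration(response=response).fit(arr[:, 0], arr[:, 1])


def predict_with_ci(
    model: LinearCalibration, x0: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Mean-response prediction ``(yhat, lower, upper)`` at a single IVDE."""
    yhat, lo, hi = model.predict_ci([x0], level=level)
    return float(yhat[0]), float(lo[0]), float(hi[0])


def test_coefficients(
    model: LinearCalibration, slope0: float = 1.0, intercept0: float = 0.0
) -> tuple[float, float]:
    return model.test_coefficients(slope0=slope0, intercept0=intercept0)


def compare_two_calibrations(
    model_a: LinearCalibration,
    model_b: LinearCalibration,
    pairs_a: Optional[Sequence[tuple[float, float]]] = None,
    pairs_b: Optional[Sequence[tuple[float, float]]] = None,
) -> tuple[float, float]:
    """Equality tests of two calibrations' slopes and intercepts.

    Pools the two training sets in one OLS with a group indicator and a
    group-by-predictor interaction; the interaction p-value tests slope
    equality and the indicator p-value intercept equality.  Returns
    ``(p_slope_eq, p_intercept_eq)``.
    """
    xa, ya = _pairs_or_training(model_a, pairs_a)
    xb, yb = _pairs_or_training(model_b, pairs_b)
    if not (np.min(xb) <= np.max(xa) and np.min(xa) <= np.max(xb)):
        import warnings

        warnings.warn("predictor supports of the two calibrations do not overlap")
    x = np.concatenate([xa, xb])
    g = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
    y = np.concatenate([ya, yb])
    design = np.column_stack([np.ones(x.size), x, g, g * x])
    ols = sm.OLS(y, design).fit()

    def _p(i: int) -> float:
        p = float(ols.pvalues[i])
        if np.isnan(p):  # identical sets: zero difference with zero SE
            return 1.0 if abs(ols.params[i]) < 1e-10 else 0.0
        return p

    return _p(3), _p(2)


def correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation of ``(x, y)`` pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.shape[0] < 3:
        raise DegenerateFitError("correlation needs n >= 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def _pairs_or_training(model: LinearCalibration, pairs):
    if pairs is not None:
        arr = np.asarray(pairs, dtype=float)
        return arr[:, 0], arr[:, 1]
    check_is_fitted(model, "x_train_")
    return model.x_train_, model.y_train_
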