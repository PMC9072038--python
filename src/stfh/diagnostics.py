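"""Model-assessment battery: information criteria, normality check,
bias-diagnostic regression, CV and efficiency-gain summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .covariance import build_full_covariance
from .exceptions import (
    ConvergenceError,
    DegenerateRegressionError,
    SampleSizeError,
    ValidationError,
)
from .panel import AreaPanel, ProximityMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .estimation import FitResult

__all__ = [
    "DiagnosticsReport",
    "information_criteria",
    "ks_normality",
    "bias_diagnostic",
    "cv_percent",
    "efficiency_gain",
    "six_number_summary",
]


@dataclass(frozen=True)
class DiagnosticsReport:
    """Collected diagnostics for one fitted model."""

    model_tag: str
    minus2ll: float
    aic: float
    bic: float
    ks_statistic: float | None = None
    ks_pvalue: float | None = None
    bias_slope: float | None = None
    bias_intercept: float | None = None
    bias_r_squared: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def information_criteria(
    fit: "FitResult", n: int | None = None
) -> tuple[float, float, float]:
    """(-2LL, AIC, BIC) from a converged REML fit.

    ``AIC = -2LL + 2k`` and ``BIC = -2LL + k log n`` with ``k`` the total
    number of estimated parameters (fixed effects + free covariance
    parameters) and ``n = m*T`` observations.  Lower is preferred.
    """
    if not fit.converged:
        raise ConvergenceError("information criteria require a converged fit")
    if n is None:
        n = fit.n_obs
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    minus2ll = -2.0 * fit.loglik
    k = fit.n_params
    return minus2ll, minus2ll + 2.0 * k, minus2ll + k * np.log(n)


def standardized_residuals(
    fit: "FitResult", panel: AreaPanel, W: ProximityMatrix | None
) -> np.ndarray:
    """Marginal residuals scaled by the fitted marginal standard deviations,
    diag(V)^{-1/2} (y - X beta_hat)."""
    use_W = W if fit.model_tag in ("sfh", "stfh") else None
    bundle = build_full_covariance(fit.tau_hat, use_W, panel.D)
    resid = panel.y_stacked - panel.X @ fit.beta_hat
    return resid / np.sqrt(np.diag(bundle.V))


def ks_normality(
    fit: "FitResult", panel: AreaPanel, W: ProximityMatrix | None = None
) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of the standardized residuals against N(0,1).

    Note the usual caveat: parameters are estimated from the same data, so
    the test is conservative (Lilliefors correction is deliberately not
    applied).
    """
    if not fit.converged:
        raise ConvergenceError("normality check requires a converged fit")
    r = standardized_residuals(fit, panel, W)
    if r.size < 5:
        raise SampleSizeError(f"need at least 5 residuals, got {r.size}")
    res = stats.kstest(r, "norm")
    return float(res.statistic), float(res.pvalue)


def bias_diagnostic(
    direct: np.ndarray, model_est: np.ndarray
) -> tuple[float, float, float]:
    """OLS of direct estimates on model-based estimates.

    Closeness of (slope, intercept) to (1, 0) is evidence that the
    model-based estimates track the direct ones without systematic bias.
    Returns (slope, intercept, r_squared).
    """
    y = np.asarray(direct, dtype=float)
    x = np.asarray(model_est, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("direct and model_est must be equal-length vectors")
    if y.size < 3:
        raise SampleSizeError(f"need at least 3 points, got {y.size}")
    if np.ptp(x) < 1e-12:
        raise DegenerateRegressionError("model estimates are constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def cv_percent(estimate: float, mse: float) -> float:
    """Percent coefficient of variation, 100*sqrt(mse)/|estimate|.

    Estimates with magnitude below 1e-8 are unstable and reported as NaN.
    """
    if mse < 0:
        raise ValidationError(f"mse must be >= 0, got {mse}")
    if abs(estimate) < 1e-8:
        return float("nan")
    return 100.0 * float(np.sqrt(mse)) / abs(float(estimate))


def six_number_summary(x: np.ndarray) -> dict[str, float]:
    """(min, Q1, mean, median, Q3, max) of a vector, NaNs dropped."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValidationError("empty vector after NaN removal")
    return {
        "min": float(np.min(x)),
        "q1": float(np.percentile(x, 25)),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "q3": float(np.percentile(x, 75)),
        "max": float(np.max(x)),
    }


def efficiency_gain(
    cv_ref: np.ndarray, cv_model: np.ndarray
) -> tuple[np.ndarray, dict[str, float]]:
    """Percent CV reduction of a model-based estimator over a reference.

    ``gain_i = 100 * (cv_ref_i - cv_model_i) / cv_ref_i``; negative gains
    (efficiency losses) are allowed and reported.  Returns the per-cell
    gains and their six-number summary.
    """
    ref = np.asarray(cv_ref, dtype=float)
    mod = np.asarray(cv_model, dtype=float)
    if ref.shape != mod.shape:
        raise ValidationError("cv vectors must be aligned")
    if np.any(ref[~np.isnan(ref)] <= 0):
        raise ValidationError("reference CV must be strictly positive")
    gains = 100.0 * (ref - mod) / ref
    return gains, six_number_summary(gains)
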