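"""Covariance structure of the area-level model and its REML log-likelihood.

The model for the stacked vector of direct estimates y (area-major,
time-minor; n = m*T) is

    y = X beta + Z1 nu1 + nu2 + eps

with
  * nu1  ~ N(0, sigma1^2 * Omega1(rho1)),   Omega1 = [(I - rho1 W)' (I - rho1 W)]^{-1}
    the m-vector of SAR(1) area effects, replicated over time by Z1,
  * nu2  ~ N(0, sigma2^2 * Omega2(rho2)),   Omega2 = I_m (x) Omega2_T
    the n-vector of stationary AR(1) area-time effects,
  * eps  ~ N(0, diag(D)) with known sampling variances D.

Hence var(y) = sigma1^2 (Omega1 (x) J_T) + sigma2^2 (I_m (x) Omega2_T) + diag(D),
where J_T is the T x T matrix of ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .exceptions import AdmissibilityError, ConditioningError, ValidationError
from .panel import AreaPanel, ProximityMatrix

__all__ = [
    "VarianceComponents",
    "CovarianceBundle",
    "sar_rho_interval",
    "build_omega2",
    "build_omega1",
    "build_full_covariance",
    "reml_loglik",
    "gls_from_cholesky",
]

_RHO_CAP = 0.999
_SAR_EPS = 1e-6


@dataclass(frozen=True)
class VarianceComponents:
    """The four covariance parameters tau = (sigma1^2, rho1, sigma2^2, rho2)."""

    sigma1_sq: float = 0.0
    rho1: float = 0.0
    sigma2_sq: float = 0.0
    rho2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma1_sq", "sigma2_sq"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise AdmissibilityError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.rho1):
            raise AdmissibilityError(f"rho1 must be finite, got {self.rho1}")
        if not (np.isfinite(self.rho2) and abs(self.rho2) < 1):
            raise AdmissibilityError(f"|rho2| must be < 1, got rho2={self.rho2}")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma1_sq, self.rho1, self.sigma2_sq, self.rho2])

    def validate_for(self, W: ProximityMatrix | None) -> None:
        """Check rho1 against the SAR-admissible interval of W."""
        if W is None:
            if self.rho1 != 0 or self.sigma1_sq != 0:
                raise AdmissibilityError(
                    "spatial parameters require a proximity matrix"
                )
            return
        lo, hi = sar_rho_interval(W)
        if not (lo < self.rho1 < hi):
            raise AdmissibilityError(
                f"rho1={self.rho1} outside SAR-admissible interval ({lo:.6g}, {hi:.6g})"
            )


@dataclass(frozen=True)
class CovarianceBundle:
    """All covariance objects of the model evaluated at one tau."""

    Omega1: np.ndarray | None  # m x m SAR structure (None without W)
    Omega2_T: np.ndarray  # T x T AR(1) block, identical across areas
    V_nu: np.ndarray  # (m + n) x (m + n) block diag(sigma1^2 Omega1, sigma2^2 Omega2)
    V_eps: np.ndarray  # n-vector of sampling variances (diagonal)
    V: np.ndarray  # n x n full covariance of y


def sar_rho_interval(W: ProximityMatrix | np.ndarray) -> tuple[float, float]:
    """Admissible open interval for the SAR autocorrelation rho1.

    For row-standardized W the largest eigenvalue is 1; I - rho1*W stays
    nonsingular for rho1 in (1/omega_min, 1) where omega_min is the smallest
    real eigenvalue.  The interval is clipped to +/-0.999 for numerical
    stability.
    """
    Wm = W.W if isinstance(W, ProximityMatrix) else np.asarray(W, dtype=float)
    eig = np.linalg.eigvals(Wm)
    real = eig[np.abs(eig.imag) < 1e-8].real
    if real.size == 0 or real.min() >= 0:
        lo = -_RHO_CAP
    else:
        lo = max(-_RHO_CAP, 1.0 / real.min() + _SAR_EPS)
    return lo, _RHO_CAP


def build_omega2(rho2: float, T: int) -> np.ndarray:
    """T x T stationary AR(1) structure: entries rho2^|t-s| / (1 - rho2^2)."""
    if T < 1:
        raise ValidationError(f"T must be >= 1, got {T}")
    if not (np.isfinite(rho2) and abs(rho2) < 1):
        raise AdmissibilityError(f"|rho2| must be < 1, got rho2={rho2}")
    lags = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    return rho2**lags / (1.0 - rho2**2)


def build_omega1(rho1: float, W: ProximityMatrix) -> np.ndarray:
    """m x m SAR(1) structure [(I - rho1 W)' (I - rho1 W)]^{-1}."""
    lo, hi = sar_rho_interval(W)
    if not (lo < rho1 < hi):
        raise AdmissibilityError(
            f"rho1={rho1} outside SAR-admissible interval ({lo:.6g}, {hi:.6g})"
        )
    m = W.m
    B = np.eye(m) - rho1 * W.W
    M = B.T @ B
    try:
        c, low = sla.cho_factor(M, lower=True)
        Omega1 = sla.cho_solve((c, low), np.eye(m))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by interval
        raise AdmissibilityError(f"I - rho1*W singular at rho1={rho1}") from exc
    return 0.5 * (Omega1 + Omega1.T)


def build_full_covariance(
    tau: VarianceComponents,
    W: ProximityMatrix | None,
    D: np.ndarray,
) -> CovarianceBundle:
    """Assemble every covariance object of the model at parameters tau.

    Parameters
    ----------
    tau : VarianceComponents
    W : ProximityMatrix or None
        Required whenever ``tau.sigma1_sq > 0`` or ``tau.rho1 != 0``.
    D : (m, T) ndarray
        Known sampling variances.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or np.any(D <= 0):
        raise ValidationError("D must be a 2-D matrix of positive variances")
    m, T = D.shape
    tau.validate_for(W)
    if W is not None and W.m != m:
        raise ValidationError(f"W has {W.m} areas but D has {m} rows")
    n = m * T

    Omega2_T = build_omega2(tau.rho2, T)
    d = D.reshape(-1)

    V = np.zeros((n, n))
    if W is not None:
        Omega1 = build_omega1(tau.rho1, W)
        V += tau.sigma1_sq * np.kron(Omega1, np.ones((T, T)))
    else:
        Omega1 = None
        V += tau.sigma1_sq * np.kron(np.eye(m), np.ones((T, T)))
    V += tau.sigma2_sq * np.kron(np.eye(m), Omega2_T)
    V[np.diag_indices_from(V)] += d
    V = 0.5 * (V + V.T)

    Om1 = Omega1 if Omega1 is not None else np.eye(m)
    V_nu = np.zeros((m + n, m + n))
    V_nu[:m, :m] = tau.sigma1_sq * Om1
    V_nu[m:, m:] = tau.sigma2_sq * np.kron(np.eye(m), Omega2_T)

    return CovarianceBundle(Omega1=Omega1, Omega2_T=Omega2_T, V_nu=V_nu, V_eps=d, V=V)


def _cholesky(V: np.ndarray, tau: VarianceComponents):
    try:
        return sla.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            f"covariance matrix numerically singular at tau={tau.as_array()}"
        ) from exc


def gls_from_cholesky(cho, X: np.ndarray, y: np.ndarray):
    """GLS pieces from a Cholesky factor of V.

    Returns ``(beta_hat, XtVinvX, resid, quad)`` where ``resid = y - X beta``
    and ``quad = resid' V^{-1} resid`` (equals the REML quadratic form y'Py).
    """
    Vinv_X = sla.cho_solve(cho, X)
    Vinv_y = sla.cho_solve(cho, y)
    XtVinvX = X.T @ Vinv_X
    XtVinvX = 0.5 * (XtVinvX + XtVinvX.T)
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    resid = y - X @ beta
    quad = float(resid @ sla.cho_solve(cho, resid))
    return beta, XtVinvX, resid, quad


def reml_loglik(
    tau: VarianceComponents,
    panel: AreaPanel,
    W: ProximityMatrix | None,
) -> float:
    """Restricted (residual) Gaussian log-likelihood at tau.

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X' V^{-1} X| + y' P y ]

    with P = V^{-1} - V^{-1} X (X'V^{-1}X)^{-1} X' V^{-1}.  The quadratic
    form is evaluated as the GLS residual sum of squares; V is factorized
    once (Cholesky) and never explicitly inverted.
    """
    bundle = build_full_covariance(tau, W, panel.D)
    cho = _cholesky(bundle.V, tau)
    n, p = panel.n, panel.p
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    X, y = panel.X, panel.y_stacked
    _, XtVinvX, _, quad = gls_from_cholesky(cho, X, y)
    sign, logdet_XtVX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise ConditioningError(
            f"X'V^-1X not positive definite at tau={tau.as_array()}"
        )
    return -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdet_V + logdet_XtVX + quad)
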