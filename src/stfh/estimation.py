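"""REML fitting, EBLUP prediction, and MSE estimation.

Three nested area-level models are supported, all expressed through the
same stacked covariance ``var(y) = sigma1^2 Z1 Omega1 Z1' + sigma2^2 Omega2
+ diag(D)``:

========  =========================  ==========================
tag       free covariance params     interpretation
========  =========================  ==========================
``fh``    sigma2_sq                  iid cell effects (classical
                                     Fay-Herriot when T = 1)
``sfh``   sigma1_sq, rho1            SAR(1) area effects, no
                                     time effects
``stfh``  sigma1_sq, rho1,           SAR(1) area effects plus
          sigma2_sq, rho2            stationary AR(1) area-time
                                     effects
========  =========================  ==========================

MSE of the EBLUP is available analytically for ``fh`` (the classical
g1 + g2 + 2*g3 decomposition) and by parametric bootstrap for all models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize

from .covariance import (
    VarianceComponents,
    build_full_covariance,
    build_omega1,
    gls_from_cholesky,
    reml_loglik,
    sar_rho_interval,
)
from .exceptions import (
    BootstrapFailureError,
    ConditioningError,
    ConvergenceError,
    ModelChoiceError,
    RankError,
    StfhError,
    ValidationError,
)
from .panel import AreaPanel, ProximityMatrix

__all__ = [
    "FitResult",
    "PredictionSet",
    "FitOptions",
    "MODEL_FREE_PARAMS",
    "gls_beta",
    "fit_model",
    "eblup",
    "mse_analytic_fh",
    "mse_bootstrap",
]

MODEL_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "fh": ("sigma2_sq",),
    "sfh": ("sigma1_sq", "rho1"),
    "stfh": ("sigma1_sq", "rho1", "sigma2_sq", "rho2"),
}

_VAR_CLAMP = 1e-10
_RHO_CAP = 0.999


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration for :func:`fit_model`.

    ``constraints`` pins named covariance parameters at fixed values and
    removes them from the free set (used e.g. to reduce the spatiotemporal
    model to the plain one).
    """

    max_iter: int = 500
    gtol: float = 1e-5
    ftol: float = 1e-8
    constraints: dict[str, float] = field(default_factory=dict)
    extra_starts: tuple[dict[str, float], ...] = ({"rho1": 0.5, "rho2": -0.3},)
    start: dict[str, float] | None = None  # overrides the default start


@dataclass(frozen=True)
class FitResult:
    """REML fit of one model."""

    model_tag: str
    beta_hat: np.ndarray
    beta_cov: np.ndarray
    tau_hat: VarianceComponents
    loglik: float
    n_params: int
    converged: bool
    n_iter: int
    free_names: tuple[str, ...]
    n_obs: int = 0
    boundary: tuple[str, ...] = ()
    trace: str = ""

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.loglik):
            raise ConvergenceError("converged fit must have finite log-likelihood")
        bc = np.asarray(self.beta_cov, dtype=float)
        if not np.allclose(bc, bc.T, atol=1e-8):
            raise ValidationError("beta covariance must be symmetric")

    @property
    def p(self) -> int:
        return len(np.atleast_1d(self.beta_hat))


@dataclass
class PredictionSet:
    """Per-cell predictions and their accuracy measures.

    ``table`` has one row per (area, time) in stacking order with columns
    ``area_id, time, direct, var_direct, eblup, mse, root_mse, cv_direct,
    cv_model, model_tag, mse_method``.  ``mse`` is NaN until an MSE method
    has been applied.
    """

    table: pd.DataFrame
    model_tag: str
    mse_method: str

    def __post_init__(self) -> None:
        mse = self.table["mse"].to_numpy()
        ok = np.isnan(mse) | (mse >= 0)
        if not ok.all():
            raise ValidationError("negative MSE in prediction set")

    @property
    def eblup(self) -> np.ndarray:
        return self.table["eblup"].to_numpy()

    @property
    def mse(self) -> np.ndarray:
        return self.table["mse"].to_numpy()

    def at_time(self, time_id: str) -> pd.DataFrame:
        return self.table[self.table["time"] == str(time_id)]


def _cv(estimate: np.ndarray, mse: np.ndarray) -> np.ndarray:
    """100 * sqrt(mse) / |estimate|; NaN where the estimate is ~0."""
    est = np.abs(np.asarray(estimate, dtype=float))
    out = np.full(est.shape, np.nan)
    stable = est >= 1e-8
    out[stable] = 100.0 * np.sqrt(np.asarray(mse, dtype=float)[stable]) / est[stable]
    return out


def _check_model_inputs(
    panel: AreaPanel, W: ProximityMatrix | None, model_tag: str
) -> None:
    if model_tag not in MODEL_FREE_PARAMS:
        raise ModelChoiceError(
            f"unknown model tag {model_tag!r}; choose from {sorted(MODEL_FREE_PARAMS)}"
        )
    if model_tag in ("sfh", "stfh") and W is None:
        raise ModelChoiceError(f"model {model_tag!r} requires a proximity matrix")
    if model_tag == "stfh" and panel.T < 2:
        raise ModelChoiceError("spatiotemporal model requires T >= 2 time points")
    if W is not None and W.m != panel.m:
        raise ValidationError(
            f"proximity matrix has {W.m} areas but panel has {panel.m}"
        )


def gls_beta(
    tau: VarianceComponents,
    panel: AreaPanel,
    W: ProximityMatrix | None,
) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed effects at given covariance parameters.

    Returns ``beta_hat = (X'V^-1X)^-1 X'V^-1 y`` and its covariance
    ``(X'V^-1X)^-1``.
    """
    if np.linalg.matrix_rank(panel.X) < panel.p:
        _, R = np.linalg.qr(panel.X)
        dep = np.where(np.abs(np.diag(R)) < 1e-10)[0].tolist()
        raise RankError(f"design matrix rank deficient; dependent columns: {dep}")
    bundle = build_full_covariance(tau, W, panel.D)
    cho = sla.cho_factor(bundle.V, lower=True)
    beta, XtVinvX, _, _ = gls_from_cholesky(cho, panel.X, panel.y_stacked)
    beta_cov = np.linalg.inv(XtVinvX)
    return beta, 0.5 * (beta_cov + beta_cov.T)


# ---------------------------------------------------------------------------
# parameter transforms: optimize on an unconstrained scale
# ---------------------------------------------------------------------------


class _ParamMap:
    """Bijection between free covariance parameters and R^k.

    Variances go through log, autocorrelations through a scaled tanh onto
    their admissible open intervals.
    """

    def __init__(
        self,
        free: tuple[str, ...],
        fixed: dict[str, float],
        rho1_interval: tuple[float, float],
    ):
        self.free = free
        self.fixed = fixed
        self.rho1_lo, self.rho1_hi = rho1_interval

    def _rho1_to_z(self, r: float) -> float:
        u = (r - self.rho1_lo) / (self.rho1_hi - self.rho1_lo)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        return float(np.arctanh(2 * u - 1))

    def _z_to_rho1(self, z: float) -> float:
        u = 0.5 * (np.tanh(z) + 1.0)
        return float(self.rho1_lo + (self.rho1_hi - self.rho1_lo) * u)

    def to_z(self, tau: dict[str, float]) -> np.ndarray:
        z = []
        for name in self.free:
            v = tau[name]
            if name.startswith("sigma"):
                z.append(np.log(max(v, 1e-12)))
            elif name == "rho1":
                z.append(self._rho1_to_z(v))
            else:  # rho2
                z.append(float(np.arctanh(np.clip(v / _RHO_CAP, -1 + 1e-12, 1 - 1e-12))))
        return np.array(z)

    def to_tau(self, z: np.ndarray) -> VarianceComponents:
        vals = dict(self.fixed)
        for name, zi in zip(self.free, z):
            if name.startswith("sigma"):
                vals[name] = float(np.exp(np.clip(zi, -40.0, 40.0)))
            elif name == "rho1":
                vals[name] = self._z_to_rho1(zi)
            else:
                vals[name] = float(_RHO_CAP * np.tanh(zi))
        vals.setdefault("sigma1_sq", 0.0)
        vals.setdefault("rho1", 0.0)
        vals.setdefault("sigma2_sq", 0.0)
        vals.setdefault("rho2", 0.0)
        return VarianceComponents(**vals)


def fit_model(
    panel: AreaPanel,
    W: ProximityMatrix | None = None,
    model_tag: str = "stfh",
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one of the nested models by REML.

    The restricted log-likelihood is maximized over the model's free
    covariance parameters on a transformed (unconstrained) scale by L-BFGS-B,
    with a Nelder-Mead polish/fallback, from two starting points.  Variance
    estimates below 1e-10 are clamped to 0 and flagged as boundary.
    """
    options = options or FitOptions()
    _check_model_inputs(panel, W, model_tag)

    free = tuple(
        n for n in MODEL_FREE_PARAMS[model_tag] if n not in options.constraints
    )
    fixed = {
        n: float(options.constraints.get(n, 0.0))
        for n in ("sigma1_sq", "rho1", "sigma2_sq", "rho2")
        if n not in free
    }
    use_W = W if model_tag in ("sfh", "stfh") else None
    rho1_iv = sar_rho_interval(use_W) if use_W is not None else (-_RHO_CAP, _RHO_CAP)
    pmap = _ParamMap(free, fixed, rho1_iv)

    def neg_loglik(z: np.ndarray) -> float:
        try:
            tau = pmap.to_tau(z)
            ll = reml_loglik(tau, panel, use_W)
        except (ConditioningError, StfhError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    s0 = 0.5 * float(np.median(panel.D))
    base_start = {"sigma1_sq": s0, "rho1": 0.0, "sigma2_sq": s0, "rho2": 0.0}
    if options.start:
        base_start.update({k: float(v) for k, v in options.start.items()})
    starts = [dict(base_start)]
    for alt in options.extra_starts:
        st = dict(base_start)
        st.update(alt)
        # keep alternative rho1 inside the admissible interval
        st["rho1"] = float(np.clip(st["rho1"], rho1_iv[0] + 1e-3, rho1_iv[1] - 1e-3))
        starts.append(st)

    best: Any = None
    n_iter = 0
    trace_lines = []
    if not free:
        z_opt = np.array([])
        converged = True
        trace_lines.append("no free covariance parameters; GLS only")
    else:
        for k, start in enumerate(starts):
            z0 = pmap.to_z(start)
            if np.any(neg_loglik(z0) >= 1e12):
                trace_lines.append(f"start {k}: non-finite likelihood, skipped")
                continue
            res = optimize.minimize(
                neg_loglik,
                z0,
                method="L-BFGS-B",
                options={
                    "maxiter": options.max_iter,
                    "ftol": options.ftol * 1e-4,
                    "gtol": options.gtol,
                },
            )
            n_iter += int(res.nit)
            if (not res.success) or not np.isfinite(res.fun):
                res_nm = optimize.minimize(
                    neg_loglik,
                    res.x if np.isfinite(res.fun) else z0,
                    method="Nelder-Mead",
                    options={
                        "maxiter": options.max_iter,
                        "fatol": options.ftol,
                        "xatol": 1e-8,
                    },
                )
                n_iter += int(res_nm.nit)
                if np.isfinite(res_nm.fun) and res_nm.fun <= res.fun:
                    res = res_nm
            trace_lines.append(
                f"start {k}: f={res.fun:.8g} success={res.success} nit={res.nit}"
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or best.fun >= 1e12:
            raise ConvergenceError(
                "non-finite REML likelihood at every starting point"
            )
        z_opt = np.asarray(best.x, dtype=float)
        converged = bool(best.success) and np.isfinite(best.fun)

    tau_hat = pmap.to_tau(z_opt)

    # clamp tiny variances to the boundary
    vals = {
        "sigma1_sq": tau_hat.sigma1_sq,
        "rho1": tau_hat.rho1,
        "sigma2_sq": tau_hat.sigma2_sq,
        "rho2": tau_hat.rho2,
    }
    boundary = []
    for vn in ("sigma1_sq", "sigma2_sq"):
        if 0 < vals[vn] < _VAR_CLAMP:
            vals[vn] = 0.0
            boundary.append(vn)
    tau_hat = VarianceComponents(**vals)

    loglik = reml_loglik(tau_hat, panel, use_W)
    beta_hat, beta_cov = gls_beta(tau_hat, panel, use_W)

    return FitResult(
        model_tag=model_tag,
        beta_hat=beta_hat,
        beta_cov=beta_cov,
        tau_hat=tau_hat,
        loglik=loglik,
        n_params=panel.p + len(free),
        converged=converged,
        n_iter=n_iter,
        free_names=free,
        n_obs=panel.n,
        boundary=tuple(boundary),
        trace="\n".join(trace_lines),
    )


def _prediction_table(
    panel: AreaPanel,
    theta: np.ndarray,
    mse: np.ndarray,
    model_tag: str,
    mse_method: str,
) -> PredictionSet:
    m, T = panel.m, panel.T
    area = np.repeat(panel.area_ids, T)
    time = np.tile(panel.time_ids, m)
    direct = panel.y_stacked
    var_direct = panel.D_stacked
    table = pd.DataFrame(
        {
            "area_id": area,
            "time": time,
            "direct": direct,
            "var_direct": var_direct,
            "eblup": theta,
            "mse": mse,
            "root_mse": np.sqrt(np.where(np.isnan(mse), np.nan, mse)),
            "cv_direct": _cv(direct, var_direct),
            "cv_model": _cv(theta, mse),
            "model_tag": model_tag,
            "mse_method": mse_method,
        }
    )
    return PredictionSet(table=table, model_tag=model_tag, mse_method=mse_method)


def _eblup_vector(
    tau: VarianceComponents,
    beta: np.ndarray,
    panel: AreaPanel,
    W: ProximityMatrix | None,
) -> np.ndarray:
    """theta_hat = X beta + (V - V_eps) V^{-1} (y - X beta) = y - V_eps V^{-1} r."""
    bundle = build_full_covariance(tau, W, panel.D)
    cho = sla.cho_factor(bundle.V, lower=True)
    resid = panel.y_stacked - panel.X @ beta
    return panel.y_stacked - bundle.V_eps * sla.cho_solve(cho, resid)


def eblup(
    fit: FitResult,
    panel: AreaPanel,
    W: ProximityMatrix | None = None,
) -> PredictionSet:
    """Empirical best linear unbiased prediction for every cell.

    The prediction is a matrix-weighted compromise between the direct
    estimate and the synthetic regression part X beta_hat; no MSE is
    attached (use :func:`mse_analytic_fh` or :func:`mse_bootstrap`).
    """
    if not fit.converged:
        raise ConvergenceError("refusing to predict from a non-converged fit")
    use_W = W if fit.model_tag in ("sfh", "stfh") else None
    _check_model_inputs(panel, W, fit.model_tag)
    theta = _eblup_vector(fit.tau_hat, fit.beta_hat, panel, use_W)
    mse = np.full(panel.n, np.nan)
    return _prediction_table(panel, theta, mse, fit.model_tag, "none")


def mse_analytic_fh(fit: FitResult, panel: AreaPanel) -> pd.DataFrame:
    """Classical analytic MSE decomposition for the ``fh`` model.

    Per cell: ``g1 = gamma * D``, ``g2 = (1-gamma)^2 x'(X'V^-1X)^-1 x``,
    ``g3 = D^2 (sigma^2 + D)^-3 var(sigma^2)`` with the asymptotic REML
    variance ``var(sigma^2) = 2 / sum_j (sigma^2 + D_j)^-2``, and
    ``mse = g1 + g2 + 2*g3``.

    Returns a data frame with columns g1, g2, g3, mse in stacking order.
    """
    if fit.model_tag != "fh":
        raise ModelChoiceError(
            "analytic MSE is available for the 'fh' model only; "
            "use mse_bootstrap for spatial/spatiotemporal fits"
        )
    if not fit.converged:
        raise ConvergenceError("refusing MSE from a non-converged fit")
    sigma2 = fit.tau_hat.sigma2_sq
    d = panel.D_stacked
    gamma = sigma2 / (sigma2 + d)
    g1 = gamma * d
    # (X'V^-1X)^-1 is exactly the fitted beta covariance
    A = fit.beta_cov
    g2 = (1.0 - gamma) ** 2 * np.einsum("ij,jk,ik->i", panel.X, A, panel.X)
    var_sigma = 2.0 / float(np.sum((sigma2 + d) ** -2))
    g3 = d**2 / (sigma2 + d) ** 3 * var_sigma
    mse = g1 + g2 + 2.0 * g3
    out = pd.DataFrame(
        {
            "area_id": np.repeat(panel.area_ids, panel.T),
            "time": np.tile(panel.time_ids, panel.m),
            "g1": g1,
            "g2": g2,
            "g3": g3,
            "mse": mse,
        }
    )
    return out


def mse_analytic_fh_predictions(fit: FitResult, panel: AreaPanel) -> PredictionSet:
    """EBLUPs with the analytic FH MSE attached."""
    comps = mse_analytic_fh(fit, panel)
    theta = _eblup_vector(fit.tau_hat, fit.beta_hat, panel, None)
    return _prediction_table(
        panel, theta, comps["mse"].to_numpy(), fit.model_tag, "analytic"
    )


def _simulate_effects(
    tau: VarianceComponents,
    W: ProximityMatrix | None,
    m: int,
    T: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (nu1, nu2) from the fitted random-effect laws.

    nu1 is sampled as (I - rho1 W)^{-1} e with e ~ N(0, sigma1^2 I), which
    has exactly covariance sigma1^2 Omega1; nu2 row-wise by the stationary
    AR(1) recursion.
    """
    if tau.sigma1_sq > 0 and W is not None:
        e = rng.standard_normal(m) * np.sqrt(tau.sigma1_sq)
        nu1 = np.linalg.solve(np.eye(m) - tau.rho1 * W.W, e)
    else:
        nu1 = np.zeros(m)
    nu2 = np.zeros((m, T))
    if tau.sigma2_sq > 0:
        s = np.sqrt(tau.sigma2_sq)
        nu2[:, 0] = rng.standard_normal(m) * s / np.sqrt(1.0 - tau.rho2**2)
        for t in range(1, T):
            nu2[:, t] = tau.rho2 * nu2[:, t - 1] + rng.standard_normal(m) * s
    return nu1, nu2


def mse_bootstrap(
    fit: FitResult,
    panel: AreaPanel,
    W: ProximityMatrix | None,
    B: int,
    seed: int,
    refit: bool = True,
    max_fail_frac: float = 0.1,
) -> PredictionSet:
    """Parametric bootstrap MSE for the EBLUP.

    For each replicate, new random effects and sampling errors are drawn
    from the fitted model, the synthetic truth ``theta* = X beta_hat + Z1
    nu1* + nu2*`` recorded, the model refitted (or, with ``refit=False``,
    the fitted covariance parameters held fixed and only beta re-estimated),
    and the squared prediction error accumulated.

    Replicates whose refit fails are dropped and redrawn up to
    ``max_fail_frac * B`` failures; beyond that an error reports the
    observed failure fraction.
    """
    if B < 1:
        raise ValidationError(f"bootstrap replicate count must be >= 1, got {B}")
    if not fit.converged:
        raise ConvergenceError("refusing bootstrap from a non-converged fit")
    _check_model_inputs(panel, W, fit.model_tag)
    use_W = W if fit.model_tag in ("sfh", "stfh") else None

    m, T, n = panel.m, panel.T, panel.n
    tau, beta = fit.tau_hat, fit.beta_hat
    Xb = panel.X @ beta
    sd_eps = np.sqrt(panel.D_stacked)

    fixed_cho = None
    if not refit:
        bundle = build_full_covariance(tau, use_W, panel.D)
        fixed_cho = sla.cho_factor(bundle.V, lower=True)
        fixed_veps = bundle.V_eps

    sq_err = np.zeros(n)
    done = 0
    failures = 0
    max_fail = int(np.floor(max_fail_frac * B))
    rep_index = 0
    opts = FitOptions(
        extra_starts=(),
        start={
            "sigma1_sq": max(tau.sigma1_sq, 1e-6),
            "rho1": tau.rho1,
            "sigma2_sq": max(tau.sigma2_sq, 1e-6),
            "rho2": tau.rho2,
        },
    )

    while done < B:
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep_index)))
        rep_index += 1
        nu1, nu2 = _simulate_effects(tau, use_W, m, T, rng)
        theta_star = Xb + np.repeat(nu1, T) + nu2.reshape(-1)
        y_star = theta_star + rng.standard_normal(n) * sd_eps
        panel_star = AreaPanel(
            area_ids=panel.area_ids,
            time_ids=panel.time_ids,
            y=y_star.reshape(m, T),
            D=panel.D,
            X=panel.X,
        )
        if refit:
            try:
                fit_star = fit_model(panel_star, use_W, fit.model_tag, opts)
                if not fit_star.converged:
                    raise ConvergenceError("bootstrap refit did not converge")
                theta_hat = _eblup_vector(
                    fit_star.tau_hat, fit_star.beta_hat, panel_star, use_W
                )
            except StfhError:
                failures += 1
                if failures > max_fail:
                    raise BootstrapFailureError(
                        f"{failures}/{rep_index} bootstrap replicates failed "
                        f"(cap {max_fail_frac:.0%} of B={B})"
                    )
                continue
        else:
            beta_star, _, resid, _ = gls_from_cholesky(
                fixed_cho, panel.X, y_star
            )
            theta_hat = y_star - fixed_veps * sla.cho_solve(fixed_cho, resid)
        sq_err += (theta_hat - theta_star) ** 2
        done += 1

    mse = sq_err / B
    theta = _eblup_vector(tau, beta, panel, use_W)
    method = f"bootstrap B={B}" + ("" if refit else " (no refit)")
    return _prediction_table(panel, theta, mse, fit.model_tag, method)
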