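"""Synthetic zone x year panels with known truth.

Generates contiguity graphs, covariates, heteroscedastic sampling
variances, and panels drawn exactly from the model:

    y_it = x_it' beta + nu1_i + nu2_it + eps_it

with nu1 ~ SAR(1), nu2 row-wise stationary AR(1), eps ~ N(0, D_it).

Random number contract: a single root seed; independent sub-streams are
derived per replicate and per component (graph, covariates, variances,
nu1, nu2, eps), so toggling one component never perturbs the draws of the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .covariance import VarianceComponents, build_omega1
from .exceptions import StfhError, ValidationError
from .panel import AreaPanel, ProximityMatrix

__all__ = [
    "SimulationScenario",
    "SyntheticTruth",
    "make_proximity",
    "simulate_panel",
    "recovery_experiment",
    "default_scenario",
]

# component tags for sub-stream derivation
_STREAMS = {"graph": 0, "covariates": 1, "variances": 2, "nu1": 3, "nu2": 4, "eps": 5}


def _rng(seed: int, component: str, replicate: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), _STREAMS[component], int(replicate)))
    )


@dataclass(frozen=True)
class SimulationScenario:
    """Full description of one synthetic data-generating process."""

    m: int = 83
    T: int = 4
    p: int = 2
    graph_kind: str = "random-planar"  # chain | grid | random-planar | supplied
    grid_shape: tuple[int, int] | None = None
    beta: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.5]))
    tau: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(0.02, 0.9, 0.01, -0.6)
    )
    var_bounds: tuple[float, float] = (0.005, 0.05)
    covariate_bounds: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    W: ProximityMatrix | None = None  # only for graph_kind="supplied"

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.m < 2:
            raise ValidationError(f"need m >= 2 areas, got {self.m}")
        if self.T < 1:
            raise ValidationError(f"need T >= 1, got {self.T}")
        if len(self.beta) != self.p:
            raise ValidationError(
                f"beta has length {len(self.beta)}, expected p = {self.p}"
            )
        a, b = self.var_bounds
        if not (0 < a <= b):
            raise ValidationError("sampling-variance bounds must satisfy 0 < a <= b")
        if self.graph_kind == "supplied" and self.W is None:
            raise ValidationError("graph_kind 'supplied' requires W")


@dataclass(frozen=True)
class SyntheticTruth:
    """The latent quantities behind one simulated panel."""

    theta: np.ndarray  # m x T true small-area quantities
    nu1: np.ndarray  # m spatial effects
    nu2: np.ndarray  # m x T temporal effects
    eps: np.ndarray  # m x T sampling errors
    beta: np.ndarray
    tau: VarianceComponents
    seed: int


def _chain_adjacency(m: int) -> np.ndarray:
    A = np.zeros((m, m))
    idx = np.arange(m - 1)
    A[idx, idx + 1] = 1.0
    A[idx + 1, idx] = 1.0
    return A


def _grid_adjacency(rows: int, cols: int) -> np.ndarray:
    m = rows * cols
    A = np.zeros((m, m))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                A[i, i + 1] = A[i + 1, i] = 1.0
            if r + 1 < rows:
                A[i, i + cols] = A[i + cols, i] = 1.0
    return A


def _planar_adjacency(m: int, seed: int) -> np.ndarray:
    """Delaunay triangulation of seeded uniform points: planar, connected."""
    rng = _rng(seed, "graph")
    pts = rng.uniform(size=(m, 2))
    tri = Delaunay(pts)
    A = np.zeros((m, m))
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            A[i, j] = A[j, i] = 1.0
    return A


def make_proximity(
    graph_kind: str,
    m: int | None = None,
    grid_shape: tuple[int, int] | None = None,
    seed: int = 0,
    area_ids: list[str] | None = None,
) -> ProximityMatrix:
    """Generate a connected contiguity structure and row-standardize it.

    ``chain``: path graph on m nodes; ``grid``: rook contiguity on
    rows x cols; ``random-planar``: Delaunay triangulation of m seeded
    uniform points.  Deterministic given the seed.
    """
    if graph_kind == "chain":
        if m is None or m < 2:
            raise ValidationError("chain graph needs m >= 2")
        A = _chain_adjacency(m)
    elif graph_kind == "grid":
        if grid_shape is None:
            raise ValidationError("grid graph needs grid_shape=(rows, cols)")
        rows, cols = grid_shape
        if rows < 1 or cols < 1 or rows * cols < 2:
            raise ValidationError("grid dims must be >= 1 with at least 2 cells")
        m = rows * cols
        A = _grid_adjacency(rows, cols)
    elif graph_kind == "random-planar":
        if m is None or m < 3:
            raise ValidationError("random-planar graph needs m >= 3")
        A = _planar_adjacency(m, seed)
    else:
        raise ValidationError(f"unknown graph kind {graph_kind!r}")
    if np.any(A.sum(axis=1) == 0):
        raise ValidationError("generated graph has an isolated node")
    ids = area_ids if area_ids is not None else [f"Z{i+1:03d}" for i in range(m)]
    return ProximityMatrix.from_adjacency(A, ids)


def _scenario_w(scenario: SimulationScenario) -> ProximityMatrix:
    if scenario.graph_kind == "supplied":
        return scenario.W  # type: ignore[return-value]
    return make_proximity(
        scenario.graph_kind,
        m=scenario.m,
        grid_shape=scenario.grid_shape,
        seed=scenario.seed,
    )


def simulate_panel(
    scenario: SimulationScenario, replicate: int = 0
) -> tuple[AreaPanel, SyntheticTruth, ProximityMatrix]:
    """Draw one panel from the scenario's data-generating process.

    The spatial effects are drawn with exact covariance
    ``sigma1^2 Omega1(rho1)`` via ``nu1 = (I - rho1 W)^{-1} e``; the AR(1)
    effects start from the stationary law so their covariance is exactly
    ``sigma2^2 Omega2(rho2)`` at every t.  Covariates are time-constant
    (drawn once per area) with an intercept column.
    """
    W = _scenario_w(scenario)
    m, T, p = scenario.m, scenario.T, scenario.p
    tau = scenario.tau
    tau.validate_for(W)  # inadmissible rho1 for this W fails here
    if tau.sigma1_sq > 0:
        build_omega1(tau.rho1, W)

    seed = scenario.seed
    rng_x = _rng(seed, "covariates", replicate)
    rng_d = _rng(seed, "variances", replicate)
    rng_n1 = _rng(seed, "nu1", replicate)
    rng_n2 = _rng(seed, "nu2", replicate)
    rng_e = _rng(seed, "eps", replicate)

    # intercept + (p-1) time-constant area covariates, replicated over T
    lo, hi = scenario.covariate_bounds
    x_area = rng_x.uniform(lo, hi, size=(m, p - 1)) if p > 1 else np.empty((m, 0))
    X = np.column_stack([np.ones(m * T), np.repeat(x_area, T, axis=0)])

    a, b = scenario.var_bounds
    D = rng_d.uniform(a, b, size=(m, T))

    if tau.sigma1_sq > 0:
        e1 = rng_n1.standard_normal(m) * np.sqrt(tau.sigma1_sq)
        nu1 = np.linalg.solve(np.eye(m) - tau.rho1 * W.W, e1)
    else:
        nu1 = np.zeros(m)

    nu2 = np.zeros((m, T))
    if tau.sigma2_sq > 0:
        s = np.sqrt(tau.sigma2_sq)
        nu2[:, 0] = rng_n2.standard_normal(m) * s / np.sqrt(1.0 - tau.rho2**2)
        for t in range(1, T):
            nu2[:, t] = tau.rho2 * nu2[:, t - 1] + rng_n2.standard_normal(m) * s

    eps = rng_e.standard_normal((m, T)) * np.sqrt(D)

    theta = (X @ scenario.beta).reshape(m, T) + nu1[:, None] + nu2
    y = theta + eps

    panel = AreaPanel(
        area_ids=W.area_ids,
        time_ids=[str(2000 + t) for t in range(T)],
        y=y,
        D=D,
        X=X,
    )
    truth = SyntheticTruth(
        theta=theta, nu1=nu1, nu2=nu2, eps=eps,
        beta=scenario.beta, tau=tau, seed=seed,
    )
    return panel, truth, W


def default_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """Scenario mirroring the study's shape: 83 areas, 4 periods,
    heteroscedastic variances, small spatial variance with strong positive
    spatial correlation and moderate negative temporal correlation."""
    base = SimulationScenario(seed=seed)
    return replace(base, **overrides) if overrides else base


def recovery_experiment(
    scenario: SimulationScenario,
    n_reps: int,
    seed: int | None = None,
    models: tuple[str, ...] = ("stfh",),
    bootstrap_B: int = 0,
    refit_bootstrap: bool = False,
) -> pd.DataFrame:
    """Repeatedly simulate-and-fit; summarize estimator performance.

    Per replicate the panel is simulated, each requested model fitted and
    its EBLUP computed; reported per model are the covariance-parameter and
    beta estimates, the mean squared prediction error of the EBLUP and of
    the direct estimator against the simulated truth, and (optionally) the
    mean bootstrap MSE for calibration checks.  Deterministic given seed.
    """
    from .estimation import eblup, fit_model, mse_bootstrap

    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    if seed is not None:
        scenario = replace(scenario, seed=seed)

    rows = []
    for rep in range(n_reps):
        try:
            panel, truth, W = simulate_panel(scenario, replicate=rep)
        except StfhError as exc:
            raise ValidationError(
                f"replicate {rep} inadmissible for scenario {scenario}"
            ) from exc
        theta_true = truth.theta.reshape(-1)
        for tag in models:
            fit = fit_model(panel, W if tag != "fh" else None, tag)
            pred = eblup(fit, panel, W)
            row = {
                "rep": rep,
                "model": tag,
                "converged": fit.converged,
                "sigma1_sq": fit.tau_hat.sigma1_sq,
                "rho1": fit.tau_hat.rho1,
                "sigma2_sq": fit.tau_hat.sigma2_sq,
                "rho2": fit.tau_hat.rho2,
                "loglik": fit.loglik,
                "mspe_eblup": float(np.mean((pred.eblup - theta_true) ** 2)),
                "mspe_direct": float(
                    np.mean((panel.y_stacked - theta_true) ** 2)
                ),
            }
            for j, bj in enumerate(fit.beta_hat):
                row[f"beta{j}"] = float(bj)
            if bootstrap_B > 0:
                bpred = mse_bootstrap(
                    fit, panel, W if tag != "fh" else None,
                    B=bootstrap_B, seed=scenario.seed + 7919 * (rep + 1),
                    refit=refit_bootstrap,
                )
                row["mean_boot_mse"] = float(np.mean(bpred.mse))
            rows.append(row)
    return pd.DataFrame(rows)
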