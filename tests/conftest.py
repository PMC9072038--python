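import numpy as np
import pytest

from stfh import (
    AreaPanel,
    ProximityMatrix,
    VarianceComponents,
    default_scenario,
    make_proximity,
    simulate_panel,
)


@pytest.fixture
def chain_w5() -> ProximityMatrix:
    return make_proximity("chain", m=5)


@pytest.fixture
def pair_w() -> ProximityMatrix:
    return ProximityMatrix.from_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])


@pytest.fixture
def small_panel() -> tuple[AreaPanel, ProximityMatrix]:
    """m=4, T=2, p=1 panel simulated from a generic spatiotemporal truth."""
    sc = default_scenario(
        seed=42, m=4, T=2, p=1, beta=np.array([1.0]),
        graph_kind="chain", tau=VarianceComponents(0.4, 0.5, 0.3, -0.4),
        var_bounds=(0.1, 0.5),
    )
    panel, _, W = simulate_panel(sc)
    return panel, W


def dense_reml_loglik(tau, panel, W):
    """Independent REML evaluation with explicit inverses and determinants.

    Only for tiny instances; kept deliberately naive (np.linalg.inv,
    np.linalg.det / slogdet on fully assembled matrices).
    """
    V = naive_full_covariance(tau, W, panel.D)
    X, y = panel.X, panel.y_stacked
    n, p = panel.n, panel.p
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtVX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ld_V + ld_X + y @ P @ y)


def naive_full_covariance(tau, W, D):
    """Element-by-element assembly of var(y) from the block definitions."""
    m, T = D.shape
    n = m * T
    if W is not None:
        B = np.eye(m) - tau.rho1 * W.W
        Omega1 = np.linalg.inv(B.T @ B)
    else:
        Omega1 = np.eye(m)
    Omega2 = np.empty((T, T))
    for t in range(T):
        for s in range(T):
            Omega2[t, s] = tau.rho2 ** abs(t - s) / (1 - tau.rho2**2)
    V = np.zeros((n, n))
    for i in range(m):
        for t in range(T):
            for j in range(m):
                for s in range(T):
                    r, c = i * T + t, j * T + s
                    V[r, c] = tau.sigma1_sq * Omega1[i, j]
                    if i == j:
                        V[r, c] += tau.sigma2_sq * Omega2[t, s]
                        if t == s:
                            V[r, c] += D[i, t]
    return V
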