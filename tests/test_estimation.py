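import dataclasses

import numpy as np
import pytest

from stfh import (
    AreaPanel,
    FitOptions,
    VarianceComponents,
    default_scenario,
    eblup,
    fit_model,
    gls_beta,
    make_proximity,
    mse_analytic_fh,
    mse_bootstrap,
    reml_loglik,
    simulate_panel,
)
from stfh.estimation import FitResult, _eblup_vector
from stfh.exceptions import (
    ConvergenceError,
    ModelChoiceError,
    ValidationError,
)


def fh_panel(m=20, sigma=0.5, seed=0, d_lo=0.1, d_hi=0.6):
    """Cross-sectional panel from the classical one-effect model."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(m), rng.uniform(-1, 1, m)])
    beta = np.array([1.0, 0.8])
    D = rng.uniform(d_lo, d_hi, size=(m, 1))
    u = rng.standard_normal(m) * np.sqrt(sigma)
    y = X @ beta + u + rng.standard_normal(m) * np.sqrt(D[:, 0])
    return AreaPanel([f"a{i:02d}" for i in range(m)], ["t0"], y[:, None], D, X)


def manual_fh_fit(panel, sigma2):
    """FitResult at a hand-chosen variance, beta by GLS (no optimization)."""
    tau = VarianceComponents(sigma2_sq=sigma2)
    beta, beta_cov = gls_beta(tau, panel, None)
    return FitResult(
        model_tag="fh", beta_hat=beta, beta_cov=beta_cov, tau_hat=tau,
        loglik=reml_loglik(tau, panel, None), n_params=panel.p + 1,
        converged=True, n_iter=0, free_names=("sigma2_sq",), n_obs=panel.n,
    )


class TestGlsBeta:
    def test_reduces_to_ols_with_isotropic_v(self):
        panel = fh_panel(m=15, d_lo=0.3, d_hi=0.3)
        beta, _ = gls_beta(VarianceComponents(), panel, None)
        ols = np.linalg.lstsq(panel.X, panel.y_stacked, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-10)

    def test_precision_weighted_mean(self):
        y = np.array([1.0, 2.0, 4.0])
        v = np.array([0.5, 1.0, 2.0])
        panel = AreaPanel(["a", "b", "c"], ["t"], y[:, None], v[:, None],
                          np.ones((3, 1)))
        beta, beta_cov = gls_beta(VarianceComponents(), panel, None)
        expected = np.sum(y / v) / np.sum(1 / v)
        assert beta[0] == pytest.approx(expected, abs=1e-12)
        assert beta_cov[0, 0] == pytest.approx(1 / np.sum(1 / v), abs=1e-12)

    def test_residual_orthogonality(self, small_panel):
        panel, W = small_panel
        tau = VarianceComponents(0.3, 0.4, 0.2, -0.5)
        beta, _ = gls_beta(tau, panel, W)
        from stfh.covariance import build_full_covariance

        V = build_full_covariance(tau, W, panel.D).V
        resid = panel.y_stacked - panel.X @ beta
        np.testing.assert_allclose(
            panel.X.T @ np.linalg.solve(V, resid), 0.0, atol=1e-8
        )


class TestFitModel:
    def test_fh_requires_no_w_stfh_requires_w(self, small_panel):
        panel, W = small_panel
        with pytest.raises(ModelChoiceError):
            fit_model(panel, None, "stfh")
        with pytest.raises(ModelChoiceError):
            fit_model(panel, None, "sfh")

    def test_stfh_needs_two_periods(self):
        panel = fh_panel(m=10)
        W = make_proximity("chain", m=10, area_ids=panel.area_ids)
        with pytest.raises(ModelChoiceError, match="T >= 2"):
            fit_model(panel, W, "stfh")

    def test_unknown_tag(self, small_panel):
        panel, W = small_panel
        with pytest.raises(ModelChoiceError, match="unknown"):
            fit_model(panel, W, "xyz")

    def test_fh_fit_recovers_reasonable_variance(self):
        panel = fh_panel(m=60, sigma=0.5, seed=3)
        fit = fit_model(panel, None, "fh")
        assert fit.converged
        assert 0.1 < fit.tau_hat.sigma2_sq < 1.5
        assert fit.n_params == panel.p + 1

    def test_loglik_at_optimum_beats_truth(self):
        sc = default_scenario(
            seed=8, m=30, T=3, tau=VarianceComponents(0.4, 0.6, 0.3, 0.4)
        )
        panel, _, W = simulate_panel(sc)
        fit = fit_model(panel, W, "stfh")
        assert fit.converged
        assert fit.loglik >= reml_loglik(sc.tau, panel, W) - 1e-8

    def test_null_parameter_recovery(self):
        # data with no spatial and no temporal correlation: rho2 sits near
        # zero and the spatial variance collapses to ~0 (rho1 itself is
        # unidentified once sigma1_sq = 0, so it carries no signal)
        tau0 = VarianceComponents(0.0, 0.0, 0.3, 0.0)
        sc = default_scenario(seed=21, m=50, T=4, tau=tau0)
        rows = []
        for rep in range(6):
            panel, _, W = simulate_panel(sc, replicate=rep)
            fit = fit_model(panel, W, "stfh")
            rows.append((fit.tau_hat.sigma1_sq, fit.tau_hat.rho2))
        s1s, rho2s = np.array(rows).T
        assert abs(np.median(rho2s)) < 0.15
        assert np.median(s1s) < 0.05

    def test_constraints_pin_parameters(self, small_panel):
        panel, W = small_panel
        fit = fit_model(
            panel, W, "stfh",
            FitOptions(constraints={"sigma1_sq": 0.0, "rho1": 0.0, "rho2": 0.0}),
        )
        assert fit.tau_hat.sigma1_sq == 0.0
        assert fit.tau_hat.rho1 == 0.0
        assert fit.tau_hat.rho2 == 0.0
        assert fit.free_names == ("sigma2_sq",)


class TestEblup:
    def test_zero_variances_give_pure_synthetic(self):
        panel = fh_panel(m=12, seed=5)
        fit = manual_fh_fit(panel, 0.0)
        pred = eblup(fit, panel)
        np.testing.assert_allclose(
            pred.eblup, panel.X @ fit.beta_hat, atol=1e-10
        )

    def test_classical_fh_closed_form(self):
        panel = fh_panel(m=25, seed=7)
        fit = fit_model(panel, None, "fh")
        pred = eblup(fit, panel)
        s2 = fit.tau_hat.sigma2_sq
        gamma = s2 / (s2 + panel.D_stacked)
        expected = gamma * panel.y_stacked + (1 - gamma) * (panel.X @ fit.beta_hat)
        np.testing.assert_allclose(pred.eblup, expected, atol=1e-10)

    def test_tiny_sampling_variance_recovers_direct(self):
        panel = fh_panel(m=12, seed=9)
        D = panel.D.copy()
        D[3, 0] = 1e-10
        panel2 = AreaPanel(panel.area_ids, panel.time_ids, panel.y, D, panel.X)
        fit = manual_fh_fit(panel2, 0.4)
        pred = eblup(fit, panel2)
        assert pred.eblup[3] == pytest.approx(panel2.y_stacked[3], abs=1e-8)

    def test_refuses_nonconverged_fit(self):
        panel = fh_panel(m=10)
        fit = dataclasses.replace(manual_fh_fit(panel, 0.3), converged=False)
        with pytest.raises(ConvergenceError):
            eblup(fit, panel)

    def test_compromise_between_direct_and_synthetic(self):
        panel = fh_panel(m=25, seed=13)
        fit = fit_model(panel, None, "fh")
        pred = eblup(fit, panel)
        synth = panel.X @ fit.beta_hat
        lo = np.minimum(panel.y_stacked, synth) - 1e-12
        hi = np.maximum(panel.y_stacked, synth) + 1e-12
        assert np.all((pred.eblup >= lo) & (pred.eblup <= hi))


class TestMseAnalyticFh:
    def test_g1_exact_and_nonnegative(self):
        panel = fh_panel(m=25, seed=1)
        fit = fit_model(panel, None, "fh")
        comps = mse_analytic_fh(fit, panel)
        s2 = fit.tau_hat.sigma2_sq
        gamma = s2 / (s2 + panel.D_stacked)
        np.testing.assert_allclose(comps["g1"], gamma * panel.D_stacked, atol=1e-14)
        for col in ("g1", "g2", "g3", "mse"):
            assert np.all(comps[col] >= 0)

    def test_zero_variance_drops_g1(self):
        panel = fh_panel(m=15, seed=2)
        fit = manual_fh_fit(panel, 0.0)
        comps = mse_analytic_fh(fit, panel)
        np.testing.assert_array_equal(comps["g1"], 0.0)
        np.testing.assert_allclose(
            comps["mse"], comps["g2"] + 2 * comps["g3"], atol=1e-14
        )

    def test_exchangeable_instance_has_equal_g1(self):
        m = 10
        rng = np.random.default_rng(4)
        panel = AreaPanel(
            [f"a{i}" for i in range(m)], ["t"],
            rng.standard_normal((m, 1)), np.full((m, 1), 0.5), np.ones((m, 1)),
        )
        fit = manual_fh_fit(panel, 0.3)
        comps = mse_analytic_fh(fit, panel)
        assert np.ptp(comps["g1"]) == 0.0
        assert np.ptp(comps["g2"]) == pytest.approx(0.0, abs=1e-15)

    def test_g2_shrinks_with_m(self):
        g2_means = []
        for m in (20, 80):
            panel = fh_panel(m=m, seed=6)
            fit = fit_model(panel, None, "fh")
            g2_means.append(mse_analytic_fh(fit, panel)["g2"].mean())
        assert g2_means[1] < g2_means[0]

    def test_rejects_non_fh_fit(self, small_panel):
        panel, W = small_panel
        fit = fit_model(panel, W, "stfh")
        with pytest.raises(ModelChoiceError, match="bootstrap"):
            mse_analytic_fh(fit, panel)

    def test_monte_carlo_mse_oracle(self):
        # analytic MSE tracks the empirical MSE of the EBLUP (scaled-down
        # version of the large-replicate calibration)
        m, sigma = 40, 0.4
        rng = np.random.default_rng(100)
        X = np.column_stack([np.ones(m), rng.uniform(-1, 1, m)])
        beta = np.array([1.0, 0.5])
        D = rng.uniform(0.2, 0.8, size=(m, 1))
        n_reps = 200
        err2 = np.zeros(m)
        analytic = np.zeros(m)
        ids = [f"a{i:02d}" for i in range(m)]
        for _ in range(n_reps):
            theta = X @ beta + rng.standard_normal(m) * np.sqrt(sigma)
            y = theta + rng.standard_normal(m) * np.sqrt(D[:, 0])
            panel = AreaPanel(ids, ["t"], y[:, None], D, X)
            fit = fit_model(panel, None, "fh")
            pred = eblup(fit, panel)
            err2 += (pred.eblup - theta) ** 2
            analytic += mse_analytic_fh(fit, panel)["mse"].to_numpy()
        ratio = (analytic / n_reps).mean() / (err2 / n_reps).mean()
        assert 0.85 < ratio < 1.15


class TestMseBootstrap:
    def test_seeded_determinism(self):
        sc = default_scenario(seed=14, m=15, T=3,
                              tau=VarianceComponents(0.3, 0.5, 0.2, 0.3))
        panel, _, W = simulate_panel(sc)
        fit = fit_model(panel, W, "stfh")
        a = mse_bootstrap(fit, panel, W, B=20, seed=7, refit=False)
        b = mse_bootstrap(fit, panel, W, B=20, seed=7, refit=False)
        np.testing.assert_array_equal(a.mse, b.mse)
        c = mse_bootstrap(fit, panel, W, B=20, seed=8, refit=False)
        assert not np.array_equal(a.mse, c.mse)

    def test_refit_mode_deterministic(self):
        sc = default_scenario(seed=15, m=10, T=2,
                              tau=VarianceComponents(0.3, 0.5, 0.2, 0.3))
        panel, _, W = simulate_panel(sc)
        fit = fit_model(panel, W, "stfh")
        a = mse_bootstrap(fit, panel, W, B=5, seed=7, refit=True)
        b = mse_bootstrap(fit, panel, W, B=5, seed=7, refit=True)
        np.testing.assert_array_equal(a.mse, b.mse)
        assert a.mse_method == "bootstrap B=5"

    def test_invalid_b(self):
        panel = fh_panel(m=10)
        fit = manual_fh_fit(panel, 0.3)
        with pytest.raises(ValidationError, match=">= 1"):
            mse_bootstrap(fit, panel, None, B=0, seed=1)

    def test_fh_subcase_matches_analytic_g1_g2(self):
        # known tau held fixed (no refit): bootstrap MSE estimates
        # g1 + g2 and should land within 20% per area at B=500
        panel = fh_panel(m=30, sigma=0.5, seed=17, d_lo=0.2, d_hi=0.6)
        fit = manual_fh_fit(panel, 0.5)
        pred = mse_bootstrap(fit, panel, None, B=500, seed=3, refit=False)
        comps = mse_analytic_fh(fit, panel)
        target = (comps["g1"] + comps["g2"]).to_numpy()
        np.testing.assert_allclose(pred.mse, target, rtol=0.2)

    def test_relabeling_invariance_in_distribution(self):
        # permuting areas (and W) permutes the bootstrap MSE up to
        # Monte-Carlo noise; draws are stream- not label-keyed, so the
        # equality is distributional, checked at large B
        sc = default_scenario(seed=33, m=12, T=3, graph_kind="chain",
                              tau=VarianceComponents(0.4, 0.6, 0.3, -0.4))
        panel, _, W = simulate_panel(sc)
        fit = fit_model(panel, W, "stfh")
        B = 3000
        base = mse_bootstrap(fit, panel, W, B=B, seed=5, refit=False)
        perm = np.random.default_rng(0).permutation(panel.m)
        ids = [panel.area_ids[i] for i in perm]
        panel_p = AreaPanel(
            ids, panel.time_ids, panel.y[perm], panel.D[perm],
            panel.X.reshape(panel.m, panel.T, -1)[perm].reshape(panel.n, -1),
        )
        fit_p = dataclasses.replace(fit)
        pred_p = mse_bootstrap(fit_p, panel_p, W.reorder(ids), B=B, seed=5,
                               refit=False)
        mse_base = base.mse.reshape(panel.m, panel.T)[perm].reshape(-1)
        np.testing.assert_allclose(pred_p.mse, mse_base, rtol=0.25)

    def test_refuses_nonconverged(self):
        panel = fh_panel(m=10)
        fit = dataclasses.replace(manual_fh_fit(panel, 0.3), converged=False)
        with pytest.raises(ConvergenceError):
            mse_bootstrap(fit, panel, None, B=5, seed=1)
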