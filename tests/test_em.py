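"""EM-machinery checks against independent oracles.

The E-step is validated with an importance-sampling oracle over the
joint latent (uncured indicator, frailty); the M-steps against closed
stationarity conditions and derivative-free reference optimization; the
frailty update against a grid search of its objective.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import digamma, expit, logit

import curefrail as cf
import curefrail.core as core
from curefrail.data import MCFMParams, SurvivalDataset
from curefrail.em import frailty_objective, _reciprocal_weights

from conftest import random_params


def importance_sampling_estep(params, time, event, z_u=None, x_u=None, n_draws=200_000, seed=0):
    """Monte-Carlo posterior expectations of (y, w, log w, wy) for one subject.

    Samples the prior of the latent pair and weights by the observed-data
    density; returns estimates and ratio-estimator standard errors.
    """
    rng = np.random.default_rng(seed)
    theta = params.theta
    pi = float(cf.uncured_probability(params, z_u=z_u))
    eta_x = (
        float(np.atleast_1d(np.asarray(core.latency_linpred(params, x_u=x_u)))[0])
        if x_u is not None
        else 0.0
    )
    A = params.alpha * time**params.gamma * np.exp(eta_x)
    w = rng.gamma(theta, 1.0 / theta, n_draws)
    y = (rng.uniform(size=n_draws) < pi).astype(float)
    if event == 1:
        weight = y * w * np.exp(-w * A)  # density factors free of (y,w) cancel
    else:
        weight = y * np.exp(-w * A) + (1.0 - y)
    out = {}
    for name, g in (("p", y), ("a", w), ("b_dig", np.log(w)), ("c", w * y)):
        est = np.sum(weight * g) / np.sum(weight)
        resid = weight * (g - est)
        se = np.sqrt(np.sum(resid**2)) / np.sum(weight)
        out[name] = (est, se)
    return out


class TestEStep:
    def test_events_have_unit_posterior(self, rng):
        params = random_params(rng)
        data = SurvivalDataset(time=[0.5, 1.5], event=[1, 1])
        post = cf.e_step(params, data)
        np.testing.assert_array_equal(post.p, [1.0, 1.0])

    def test_certainly_cured_subject(self):
        params = MCFMParams(alpha=1, gamma=1, theta=2.0, b0=-800.0)
        post = cf.e_step(params, SurvivalDataset(time=[1.0], event=[0]))
        assert post.p[0] == pytest.approx(0.0, abs=1e-12)
        assert post.c[0] == pytest.approx(0.0, abs=1e-12)
        assert post.a[0] == pytest.approx(1.0)  # prior-mean frailty

    def test_frozen_hand_values(self, toy_params):
        post = cf.e_step(toy_params, SurvivalDataset(time=[1.0], event=[0]))
        assert post.p[0] == pytest.approx(1 / 3)
        assert post.a[0] == pytest.approx(5 / 6)
        assert post.c[0] == pytest.approx(1 / 6)
        assert post.b_dig[0] == pytest.approx(digamma(1.0) - np.log(2) / 3)

    def test_type_invariants(self, rng):
        params = random_params(rng, p1u=1, p2u=1)
        n = 40
        data = SurvivalDataset(
            time=rng.uniform(0.1, 3, n),
            event=(rng.uniform(size=n) < 0.5).astype(int),
            z_u=rng.normal(size=(n, 1)),
            x_u=rng.normal(size=(n, 1)),
        )
        post = cf.e_step(params, data)
        assert np.all(post.p[data.event == 1] == 1.0)
        assert np.all((post.c >= 0) & (post.c <= post.a + 1e-15))
        assert np.all(post.b_dig <= np.log(post.a) + 1e-12)  # Jensen

    def test_matches_importance_sampling_oracle(self, rng):
        for i in range(20):
            params = random_params(rng)
            time = float(rng.uniform(0.2, 2.5))
            event = int(rng.uniform() < 0.5)
            data = SurvivalDataset(time=[time], event=[event])
            post = cf.e_step(params, data)
            oracle = importance_sampling_estep(params, time, event, seed=1000 + i)
            for name, got in (
                ("p", post.p[0]),
                ("a", post.a[0]),
                ("b_dig", post.b_dig[0]),
                ("c", post.c[0]),
            ):
                est, se = oracle[name]
                assert got == pytest.approx(est, abs=max(3 * se, 1e-8)), name


class TestMStepIncidence:
    def test_full_shrinkage_at_large_lambda(self, rng):
        n = 60
        data = SurvivalDataset(
            time=rng.uniform(0.1, 2, n),
            event=(rng.uniform(size=n) < 0.5).astype(int),
            z_p=rng.normal(size=(n, 5)),
        )
        p = rng.uniform(0.1, 0.9, n)
        pen = cf.PenaltySpec(lambda_enet=50.0, alpha_enet=1.0)
        b0, b_u, b_p = cf.m_step_incidence(p, data, pen)
        np.testing.assert_array_equal(b_p, 0.0)
        assert b0 == pytest.approx(logit(p.mean()), abs=1e-5)

    def test_intercept_only_closed_form(self, rng):
        n = 30
        data = SurvivalDataset(
            time=rng.uniform(0.1, 2, n), event=np.zeros(n, dtype=int)
        )
        p = rng.uniform(0.05, 0.95, n)
        b0, _, _ = cf.m_step_incidence(p, data, cf.PenaltySpec(0.0))
        assert b0 == pytest.approx(logit(p.mean()), abs=1e-6)

    def test_unpenalized_matches_reference_optimizer(self, rng):
        n = 50
        data = SurvivalDataset(
            time=rng.uniform(0.1, 2, n),
            event=np.zeros(n, dtype=int),
            z_u=rng.normal(size=(n, 2)),
        )
        p = rng.uniform(0.05, 0.95, n)
        b0, b_u, _ = cf.m_step_incidence(p, data, cf.PenaltySpec(0.0))
        Z = np.column_stack([np.ones(n), data.z_u])

        def obj(b):
            eta = Z @ b
            return float(np.mean(np.logaddexp(0, eta) - p * eta))

        grad = Z.T @ (expit(Z @ np.r_[b0, b_u]) - p) / n
        assert np.max(np.abs(grad)) < 1e-6
        ref = minimize(obj, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert obj(np.r_[b0, b_u]) <= ref.fun + 1e-8


class TestMStepLatency:
    def test_full_shrinkage_at_large_lambda(self, rng):
        n = 60
        data = SurvivalDataset(
            time=rng.uniform(0.1, 2, n),
            event=(rng.uniform(size=n) < 0.7).astype(int),
            x_p=rng.normal(size=(n, 5)),
        )
        c = rng.uniform(0.2, 1.5, n)
        pen = cf.PenaltySpec(lambda_enet=50.0, alpha_enet=1.0)
        _, _, _, beta_p = cf.m_step_latency(c, data, pen)
        np.testing.assert_array_equal(beta_p, 0.0)

    def test_alpha_stationarity_closed_form(self, rng):
        n = 80
        data = SurvivalDataset(
            time=rng.uniform(0.1, 2, n),
            event=(rng.uniform(size=n) < 0.7).astype(int),
        )
        c = rng.uniform(0.2, 1.5, n)
        alpha, gamma, _, _ = cf.m_step_latency(c, data, cf.PenaltySpec(0.0))
        # at the joint optimum, alpha satisfies its own stationarity equation
        expected = data.event.sum() / np.sum(c * data.time**gamma)
        assert alpha == pytest.approx(expected, rel=1e-5)

    def test_matches_reference_optimizer_on_toy(self, rng):
        n = 50
        data = SurvivalDataset(
            time=rng.uniform(0.1, 2, n),
            event=(rng.uniform(size=n) < 0.7).astype(int),
            x_u=rng.normal(size=(n, 1)),
        )
        c = rng.uniform(0.2, 1.5, n)
        alpha, gamma, beta_u, _ = cf.m_step_latency(c, data, cf.PenaltySpec(0.0))

        def obj(v):
            a, g, b = np.exp(v[0]), np.exp(v[1]), v[2:]
            eta = data.x_u @ b
            lam = a * data.time**g * np.exp(eta)
            with np.errstate(over="ignore"):
                val = -np.sum(
                    data.event * (np.log(a * g) + (g - 1) * np.log(data.time) + eta)
                    - c * lam
                ) / n
            return val if np.isfinite(val) else 1e10

        ref = minimize(obj, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 8000})
        got = obj(np.r_[np.log(alpha), np.log(gamma), beta_u])
        assert got <= ref.fun + 1e-8

    def test_all_zero_weights_rejected(self, rng):
        data = SurvivalDataset(time=[1.0, 2.0], event=[1, 0])
        with pytest.raises(ValueError):
            cf.m_step_latency(np.zeros(2), data, cf.PenaltySpec(0.0))


class TestMStepFrailty:
    def test_unit_theta_fixed_point(self):
        n = 20
        a = np.ones(n)
        b = np.full(n, digamma(1.0))
        theta = cf.m_step_frailty(a, b, np.zeros(n, dtype=int))
        assert theta == pytest.approx(1.0, rel=1e-8)

    def test_homogeneous_population_hits_upper_bound(self):
        # sum(b - a)/n -> 0-: log(theta) - digamma(theta) > 0 for all theta
        n = 10
        a = np.ones(n)
        b = np.log(np.ones(n)) - 1e-9
        theta, flag = cf.m_step_frailty(a, b, np.zeros(n, dtype=int), return_flag=True)
        assert theta == 1e6 and flag

    def test_beats_grid_search(self, rng):
        for _ in range(5):
            n = 30
            event = (rng.uniform(size=n) < 0.4).astype(int)
            a = rng.uniform(0.3, 2.0, n)
            b = np.log(a) - rng.uniform(0.05, 1.0, n)  # Jensen-consistent
            theta = cf.m_step_frailty(a, b, event)
            grid = np.linspace(0.01, 100, 20000)
            best_grid = np.max(frailty_objective(grid, a, b, event))
            got = frailty_objective(np.array([theta]), a, b, event)[0]
            assert got >= best_grid - 1e-8

    def test_derivative_matches_numerical(self, rng):
        n = 15
        event = (rng.uniform(size=n) < 0.5).astype(int)
        a = rng.uniform(0.3, 2.0, n)
        b = np.log(a) - rng.uniform(0.05, 1.0, n)
        for theta in (0.3, 1.0, 4.0):
            h = 1e-6
            num = (
                frailty_objective(np.array([theta + h]), a, b, event)[0]
                - frailty_objective(np.array([theta - h]), a, b, event)[0]
            ) / (2 * h)
            analytic = n * (np.log(theta) + 1 - digamma(theta)) + np.sum(b - a)
            assert analytic == pytest.approx(num, rel=1e-4)


class TestAdaptiveWeights:
    def test_reciprocal_rule(self):
        w = _reciprocal_weights(np.array([0.5, -0.25, 0.0, 1.0]), "hard")
        np.testing.assert_allclose(w, [2.0, 4.0, np.inf, 1.0])

    def test_epsilon_mode(self):
        w = _reciprocal_weights(np.array([0.0]), "epsilon")
        assert w[0] == pytest.approx(1e6)

    def test_unit_coefficients_reproduce_plain_elastic_net(self):
        w = _reciprocal_weights(np.ones(4), "hard")
        np.testing.assert_array_equal(w, 1.0)

    def test_public_wrapper_uses_previous_fit(self, rng):
        params = random_params(rng, p1p=3, p2p=3)
        params.b_p = np.array([0.5, 0.0, 2.0])
        params.beta_p = np.array([1.0, 4.0, 0.0])
        fit = cf.FitResult(
            params=params,
            support_incidence=np.array([0, 2]),
            support_latency=np.array([0, 1]),
            penalty=cf.PenaltySpec(lambda_enet=0.1),
        )
        pen = cf.update_adaptive_weights(fit)
        np.testing.assert_allclose(pen.weights_incidence, [2.0, np.inf, 0.5])
        np.testing.assert_allclose(pen.weights_latency, [1.0, 0.25, np.inf])


class TestInitialization:
    def test_moment_estimates_recover_weibull(self, rng):
        # event times from a Weibull with cumulative hazard t^2 (alpha=1, gamma=2)
        n = 100_000
        t = np.sqrt(-np.log(rng.uniform(size=n)))
        data = SurvivalDataset(time=t, event=np.ones(n, dtype=int))
        params = cf.initialize_params(data)
        assert params.alpha == pytest.approx(1.0, rel=0.02)
        assert params.gamma == pytest.approx(2.0, rel=0.02)
        assert params.theta == 1.0

    def test_no_latency_covariates_gives_empty_beta(self, rng):
        data = SurvivalDataset(
            time=rng.uniform(0.1, 2, 50),
            event=(rng.uniform(size=50) < 0.5).astype(int),
        )
        params = cf.initialize_params(data)
        assert params.beta_u.size == 0

    def test_all_censored_rejected(self, rng):
        data = SurvivalDataset(time=rng.uniform(0.1, 2, 20), event=np.zeros(20, dtype=int))
        with pytest.raises(ValueError):
            cf.initialize_params(data)


class TestRunEM:
    def test_huge_lambda_reduces_to_lowdim_model(self, small_lowdim_data, rng):
        data, _ = small_lowdim_data
        noisy = SurvivalDataset(
            time=data.time,
            event=data.event,
            z_u=data.z_u,
            z_p=rng.normal(size=(data.n, 8)),
            x_u=data.x_u,
            x_p=rng.normal(size=(data.n, 8)),
        )
        pen = cf.PenaltySpec(lambda_enet=100.0, alpha_enet=1.0)
        fit_pen = cf.run_em(noisy, pen, cf.EMControl(tol=1e-7))
        fit_low = cf.run_em(data, cf.PenaltySpec(0.0), cf.EMControl(tol=1e-7))
        np.testing.assert_array_equal(fit_pen.params.b_p, 0.0)
        np.testing.assert_array_equal(fit_pen.params.beta_p, 0.0)
        np.testing.assert_allclose(fit_pen.params.b_u, fit_low.params.b_u, atol=1e-3)
        np.testing.assert_allclose(fit_pen.params.beta_u, fit_low.params.beta_u, atol=1e-3)
        assert fit_pen.params.alpha == pytest.approx(fit_low.params.alpha, rel=1e-3)

    def test_trace_nondecreasing_within_rounds(self, small_lowdim_data):
        data, _ = small_lowdim_data
        fit = cf.run_em(
            data, cf.PenaltySpec(0.0), cf.EMControl(tol=1e-7, max_iter=100)
        )
        for trace in fit.loglik_trace:
            assert np.all(np.diff(trace) >= -1e-8)

    def test_frailty_free_limit_matches_mcm(self, small_lowdim_data):
        data, _ = small_lowdim_data
        fit_big_theta = cf.run_em(
            data, cf.PenaltySpec(0.0), cf.EMControl(tol=1e-8, fix_theta=1e8)
        )
        fit_mcm = cf.run_em(
            data, cf.PenaltySpec(0.0), cf.EMControl(tol=1e-8, frailty=False)
        )
        np.testing.assert_allclose(
            fit_big_theta.params.beta_u, fit_mcm.params.beta_u, atol=1e-3
        )
        np.testing.assert_allclose(fit_big_theta.params.b_u, fit_mcm.params.b_u, atol=1e-3)
        assert fit_big_theta.params.b0 == pytest.approx(fit_mcm.params.b0, abs=1e-3)
        assert fit_big_theta.params.alpha == pytest.approx(fit_mcm.params.alpha, rel=2e-3)
        assert fit_big_theta.params.gamma == pytest.approx(fit_mcm.params.gamma, rel=2e-3)

    def test_subject_order_invariance(self, small_lowdim_data, rng):
        data, _ = small_lowdim_data
        perm = rng.permutation(data.n)
        fit_a = cf.run_em(data, cf.PenaltySpec(0.0), cf.EMControl(tol=1e-7))
        fit_b = cf.run_em(data.subset(perm), cf.PenaltySpec(0.0), cf.EMControl(tol=1e-7))
        np.testing.assert_allclose(fit_a.params.beta_u, fit_b.params.beta_u, atol=1e-6)
        assert fit_a.params.theta == pytest.approx(fit_b.params.theta, rel=1e-5)

    def test_support_recovery_moderate_dimension(self):
        design = cf.SimulationDesign(n=400, p_pen=200, s=4, v=2.5, block_size=50)
        sens, fpr = [], []
        for seed in range(3):
            data, truth = cf.simulate_dataset(design, seed=50 + seed)
            lams = cf.lambda_path(data, n_lambda=8)
            fit = cf.run_em(
                data,
                cf.PenaltySpec(lambda_enet=lams[4], alpha_enet=1.0, k_adaptive=2),
                cf.EMControl(tol=1e-4, max_iter=30, inner_max_iter=60),
            )
            m = cf.selection_metrics(truth.beta_p, fit.params.beta_p)
            sens.append(m["sensitivity"])
            fpr.append(m["fpr"])
        assert np.mean(sens) >= 0.75
        assert np.mean(fpr) <= 0.05
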