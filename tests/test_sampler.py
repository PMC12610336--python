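import numpy as np
import pytest

from fmmm.basis import make_basis, make_penalty
from fmmm.functional_data import FunctionalDataset
from fmmm.model_core import DesignCache, Hyperparameters, ModelConfig, ParameterState
from fmmm.sampler import (
    draw_prior_state,
    run_mcmc,
    simulate_observations,
    tempered_sweep,
    update_allocations,
    update_factor_scores,
    update_loadings,
    update_mean_coefficients,
    update_mixing,
    update_shrinkage,
    update_smoothing,
    update_variance,
)

from conftest import make_tiny_dataset

HYPER = Hyperparameters()


def _cache_for(state, rng, n=6):
    basis = make_basis((0.0, 1.0), state.P, min(state.P, 4))
    times = [np.linspace(0, 1, n)] * state.N
    X = rng.standard_normal((state.N, state.R)) if state.R else np.empty((state.N, 0))
    data = simulate_observations(state, times, X, basis, rng)
    return DesignCache(data, basis), basis


class TestMeanCoefficientUpdate:
    def test_matches_normal_normal_posterior(self, rng):
        """K=1, P=1 with a flat RW1 (penalty vanishes for P=1 via zero rows)
        reduces to the textbook normal-normal regression posterior."""
        # P=2 constant-regressor setup: use order=2 linear basis, single curve
        basis = make_basis((0.0, 1.0), 2, 2)
        n = 30
        t = np.linspace(0, 1, n)
        true_coef = np.array([1.0, 2.0])
        from fmmm.basis import eval_design

        S = eval_design(basis, t)
        y = S.T @ true_coef + 0.1 * rng.standard_normal(n)
        data = FunctionalDataset(["c"], [t], [y], np.empty((1, 0)))
        cache = DesignCache(data, basis)
        pen = make_penalty(2)
        st = ParameterState.zeros(1, 2, 0, 0, 1)
        st.sigma2 = 0.01
        st.tau_v[:] = 1e-8  # effectively flat RW1
        ridge = 1e-8
        draws = np.zeros((4000, 2))
        for j in range(draws.shape[0]):
            update_mean_coefficients(st, cache, pen, rng, ridge=ridge)
            draws[j] = st.v[0]
        prec = cache.SSt[0] / st.sigma2 + st.tau_v[0] * pen.DtD + ridge * np.eye(2)
        cov = np.linalg.inv(prec)
        mean = cov @ (cache.Sy[0] / st.sigma2)
        se = np.sqrt(np.diag(cov) / draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se)
        np.testing.assert_allclose(np.cov(draws.T), cov, rtol=0.15)

    def test_huge_smoothing_precision_flattens_v(self, rng):
        state, data, basis, cfg = make_tiny_dataset(rng, N=3, n=8, K=1, M=0, R=0)
        cache = DesignCache(data, basis)
        pen = make_penalty(state.P)
        state.tau_v[:] = 1e12
        update_mean_coefficients(state, cache, pen, rng, ridge=1e-6)
        assert np.ptp(state.v[0]) < 1e-3

    def test_no_data_no_proper_prior_errors(self, rng):
        data = FunctionalDataset([], [], [], np.empty((0, 0)))
        basis = make_basis((0.0, 1.0), 4, 4)
        cache = DesignCache(data, basis)
        st = ParameterState.zeros(1, 4, 0, 0, 0)
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            update_mean_coefficients(st, cache, make_penalty(4), rng, ridge=0.0)


class TestFactorScoreUpdate:
    def test_noise_dominated_reverts_to_standard_normal_prior(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=4, n=6, M=2)
        cache = DesignCache(data, basis)
        state.sigma2 = 1e12
        draws = np.array([
            update_factor_scores(state, cache, rng).chi.copy() for _ in range(3000)
        ])
        assert abs(draws.mean()) < 3 / np.sqrt(draws.size)
        assert abs(draws.var() - 1.0) < 0.1

    def test_scalar_case_matches_hand_formula(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=1, n=6, K=1, M=1, R=0)
        cache = DesignCache(data, basis)
        S = cache.S[0]
        w = S.T @ state.phi[0, :, 0]
        r = data.values[0] - S.T @ state.v[0]
        prec = 1.0 + w @ w / state.sigma2
        mean = (w @ r / state.sigma2) / prec
        draws = np.array([
            update_factor_scores(state, cache, rng).chi[0, 0] for _ in range(4000)
        ])
        assert abs(draws.mean() - mean) < 4 * np.sqrt(1 / prec / 4000)
        assert draws.var() == pytest.approx(1 / prec, rel=0.15)

    def test_zero_loadings_gives_exact_standard_normal(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=3, n=5, M=1)
        cache = DesignCache(data, basis)
        state.phi[...] = 0.0
        draws = np.array([
            update_factor_scores(state, cache, rng).chi.copy() for _ in range(2000)
        ])
        assert abs(draws.mean()) < 0.05
        assert abs(draws.var() - 1.0) < 0.1


class TestLoadingsUpdate:
    def test_unallocated_feature_reverts_to_mgp_prior(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=3, n=6, K=2, M=1)
        cache = DesignCache(data, basis)
        state.Z[:, 0] = 0.0
        state.Z[:, 1] = 1.0
        state.gamma[...] = 1.0
        state.delta[...] = 1.0
        draws = np.array([
            update_loadings(state, cache, rng).phi[0, :, 0].copy()
            for _ in range(3000)
        ])
        # feature 0 never enters the likelihood: draws follow N(0, 1)
        assert abs(draws.mean()) < 0.05
        assert abs(draws.var() - 1.0) < 0.12

    def test_infinite_prior_precision_pins_to_zero(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=3, n=6, M=1)
        cache = DesignCache(data, basis)
        state.gamma[...] = 1e14
        update_loadings(state, cache, rng)
        assert np.max(np.abs(state.phi)) < 1e-4


class TestVarianceUpdate:
    def test_zero_sse_exact_conjugate_moments(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=3, n=6, sigma2=0.0)
        cache = DesignCache(data, basis)
        n_tot = cache.n_total
        draws = np.array([
            update_variance(state, cache, HYPER, rng).sigma2 for _ in range(4000)
        ])
        shape = HYPER.alpha_0 + n_tot / 2
        expected_mean = HYPER.beta_0 / (shape - 1)
        assert np.all(draws > 0)
        assert draws.mean() == pytest.approx(expected_mean, rel=0.1)

    def test_residual_scaling_quadruples_rate(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=2, n=10, M=0, sigma2=0.0)
        # inject residuals r and 2r; mean sigma2 increments scale by 4
        base = [v.copy() for v in data.values]
        r = rng.standard_normal(10)

        def mean_sigma2(scale):
            data.values[0] = base[0] + scale * r
            cache = DesignCache(data, basis)
            local = np.random.default_rng(0)
            return np.mean([
                update_variance(state, cache, HYPER, local).sigma2
                for _ in range(3000)
            ])

        shape = HYPER.alpha_0 + 20 / 2
        inc1 = mean_sigma2(1.0) * (shape - 1) - HYPER.beta_0
        inc2 = mean_sigma2(2.0) * (shape - 1) - HYPER.beta_0
        assert inc2 / inc1 == pytest.approx(4.0, rel=0.1)


class TestShrinkageUpdate:
    def test_zero_loadings_gamma_reverts_to_prior(self, rng):
        st = ParameterState.zeros(1, 4, 2, 0, 1)
        st.phi[...] = 0.0
        draws = np.array([
            update_shrinkage(st, HYPER, rng)[0].gamma.copy() for _ in range(4000)
        ])
        # Gamma((nu+1)/2, nu/2) has mean (nu+1)/nu
        assert draws.mean() == pytest.approx((HYPER.nu_gamma + 1) / HYPER.nu_gamma,
                                             rel=0.05)

    def test_delta_conditional_matches_hand_algebra_M1(self, rng):
        P = 3
        st = ParameterState.zeros(1, P, 1, 0, 1)
        st.phi[0, :, 0] = [0.5, -1.0, 2.0]
        st.a1[:] = 2.0
        fixed_gamma = np.array([1.0, 2.0, 0.5])
        means = []
        for _ in range(6000):
            st.gamma[0, :, 0] = fixed_gamma
            st.a1[:] = 2.0
            update_shrinkage_only_delta(st, rng)
            means.append(st.delta[0, 0])
        shape = 2.0 + P / 2
        rate = 1.0 + 0.5 * np.sum(fixed_gamma * st.phi[0, :, 0] ** 2)
        assert np.mean(means) == pytest.approx(shape / rate, rel=0.05)

    def test_a_updates_accept_rate_interior(self, rng):
        st = ParameterState.zeros(2, 4, 3, 0, 1)
        st.phi = 0.3 * rng.standard_normal(st.phi.shape)
        rates = [update_shrinkage(st, HYPER, rng, step_a=0.5)[1]
                 for _ in range(500)]
        assert 0.0 < np.mean(rates) < 1.0


def update_shrinkage_only_delta(st, rng):
    """Replicate the delta draw in isolation (gamma, a held fixed)."""
    P, M = st.P, st.M
    for k in range(st.K):
        gp2 = np.sum(st.gamma[k] * st.phi[k] ** 2, axis=0)
        for j in range(M):
            tau_k = np.cumprod(st.delta[k])
            coef = np.sum(tau_k[j:] / st.delta[k, j] * gp2[j:])
            shape_j = (st.a1[k] if j == 0 else st.a2[k]) + P * (M - j) / 2.0
            st.delta[k, j] = rng.gamma(shape_j) / (1.0 + 0.5 * coef)


class TestSmoothingUpdate:
    def test_constant_v_exact_prior_rate(self, rng):
        st = ParameterState.zeros(1, 5, 0, 0, 1)
        st.v[0] = 4.2
        pen = make_penalty(5)
        draws = np.array([
            update_smoothing(st, HYPER, pen, rng).tau_v[0] for _ in range(6000)
        ])
        shape = HYPER.alpha_v + (5 - 1) / 2
        assert draws.mean() == pytest.approx(shape / HYPER.beta_v, rel=0.05)

    def test_scaling_v_scales_rate_quadratically(self, rng):
        pen = make_penalty(4)
        v = np.array([0.0, 1.0, 0.0, 2.0])

        def mean_tau(scale):
            st = ParameterState.zeros(1, 4, 0, 0, 1)
            st.v[0] = scale * v
            local = np.random.default_rng(3)
            return np.mean([
                update_smoothing(st, HYPER, pen, local).tau_v[0]
                for _ in range(6000)
            ])

        shape = HYPER.alpha_v + 1.5
        q = pen.quadratic_form(v)
        assert mean_tau(1.0) == pytest.approx(shape / (1 + q / 2), rel=0.05)
        assert mean_tau(2.0) == pytest.approx(shape / (1 + 4 * q / 2), rel=0.05)


class TestAllocationUpdate:
    def test_rows_stay_on_simplex(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=6, n=6, K=3, M=1, R=0)
        cache = DesignCache(data, basis)
        for _ in range(50):
            update_allocations(state, cache, rng, kappa=20.0)
            np.testing.assert_allclose(state.Z.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(state.Z >= 0) and np.all(state.Z <= 1)

    def test_flat_likelihood_reverts_to_dirichlet_prior(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=2, n=5, K=2, M=0, R=0)
        cache = DesignCache(data, basis)
        state.sigma2 = 1e12  # likelihood flat in z
        state.alpha3 = 3.0
        state.pi = np.array([0.5, 0.5])
        zs = []
        for j in range(20000):
            update_allocations(state, cache, rng, kappa=8.0)
            if j % 5 == 0:
                zs.append(state.Z[0, 0])
        zs = np.asarray(zs)
        # prior Dir(1.5, 1.5): mean 1/2, var = ab/((a+b)^2(a+b+1)) = 1/16
        assert abs(zs.mean() - 0.5) < 0.02
        assert abs(zs.var() - 1 / 16) < 0.01


class TestMixingUpdate:
    def test_symmetric_configuration_symmetric_pi(self, rng):
        st = ParameterState.zeros(2, 3, 0, 0, 1)
        st.Z[0] = [0.5, 0.5]
        means = []
        for j in range(20000):
            update_mixing(st, HYPER, rng, step_pi=0.6, step_alpha3=0.6)
            means.append(st.pi[0])
        assert abs(np.mean(means) - 0.5) < 0.02

    def test_alpha3_mean_decreases_in_exponential_rate(self, rng):
        def chain_mean(b):
            hyper = Hyperparameters(b_alpha3=b)
            st = ParameterState.zeros(2, 3, 0, 0, 1)
            st.Z[0] = [0.5, 0.5]
            local = np.random.default_rng(4)
            vals = []
            for _ in range(15000):
                update_mixing(st, hyper, local, step_pi=0.6, step_alpha3=0.6)
                vals.append(st.alpha3)
            return np.mean(vals)

        assert chain_mean(5.0) < chain_mean(0.5)

    def test_support_preserved(self, rng):
        st = ParameterState.zeros(3, 3, 0, 0, 4)
        st.Z = rng.dirichlet(np.ones(3), size=4)
        for _ in range(200):
            update_mixing(st, HYPER, rng)
            assert st.alpha3 > 0
            np.testing.assert_allclose(st.pi.sum(), 1.0, atol=1e-12)
            assert np.all(st.pi > 0)


class TestTemperedSweep:
    def test_empty_ladder_bitwise_equals_plain_sweep(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=4, n=6, K=2, M=1, R=0)
        cache = DesignCache(data, basis)
        s1, s2 = state.copy(), state.copy()
        r1 = np.random.default_rng(77)
        r2 = np.random.default_rng(77)
        tempered_sweep(s1, cache, r1, ladder=np.empty(0), kappa=30.0)
        update_allocations(s2, cache, r2, kappa=30.0)
        np.testing.assert_array_equal(s1.Z, s2.Z)

    def test_ladder_sweep_preserves_simplex(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=4, n=6, K=2, M=1, R=0)
        cache = DesignCache(data, basis)
        ladder = np.array([0.6, 0.3, 0.1])
        for _ in range(20):
            tempered_sweep(state, cache, rng, ladder, kappa=20.0)
            np.testing.assert_allclose(state.Z.sum(axis=1), 1.0, atol=1e-12)


class TestRunMcmc:
    def test_same_seed_identical_draws(self, rng):
        _, data, basis, _ = make_tiny_dataset(rng, N=5, n=8, K=2, M=1, R=1)
        cfg = ModelConfig(K=2, P=3, M=1, R=1, order=3, n_iter=60, burn_in=20)
        d1 = run_mcmc(data, cfg, seed=9, basis=basis)
        d2 = run_mcmc(data, cfg, seed=9, basis=basis)
        for name in d1.draws:
            np.testing.assert_array_equal(d1.draws[name], d2.draws[name])

    def test_draw_count_follows_thinning(self, rng):
        _, data, basis, _ = make_tiny_dataset(rng, N=4, n=8, K=2, M=1, R=0)
        cfg = ModelConfig(K=2, P=3, M=1, R=0, order=3, n_iter=110, burn_in=30,
                          thin=4)
        d = run_mcmc(data, cfg, seed=1, basis=basis)
        assert d.n_draws == (110 - 30) // 4

    def test_stored_states_satisfy_invariants(self, rng):
        _, data, basis, _ = make_tiny_dataset(rng, N=4, n=8, K=2, M=1, R=1)
        cfg = ModelConfig(K=2, P=3, M=1, R=1, order=3, n_iter=40, burn_in=10)
        d = run_mcmc(data, cfg, seed=2, basis=basis)
        for st in d.iter_states():
            st.validate()

    def test_hdf5_roundtrip(self, rng, tmp_path):
        _, data, basis, _ = make_tiny_dataset(rng, N=4, n=8, K=2, M=1, R=0)
        cfg = ModelConfig(K=2, P=3, M=1, R=0, order=3, n_iter=30, burn_in=10)
        d = run_mcmc(data, cfg, seed=3, basis=basis)
        from fmmm.sampler import PosteriorDraws

        d.save_hdf5(tmp_path / "d.h5")
        back = PosteriorDraws.load_hdf5(tmp_path / "d.h5")
        for name in d.draws:
            np.testing.assert_array_equal(d.draws[name], back.draws[name])
        assert back.seed == 3
        assert back.config.K == 2

    def test_single_feature_matches_penalized_regression_posterior(self, rng):
        """With K=1, R=0, M=0 the model is Bayesian penalized basis regression;
        the posterior mean curve must match the analytic ridge/GP solution
        conditional on the noise and smoothing precisions."""
        from fmmm.basis import eval_design

        basis = make_basis((0.0, 1.0), 5, 3)
        n, N = 20, 3
        t = np.linspace(0, 1, n)
        S = eval_design(basis, t)
        coef_true = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        sigma = 0.2
        values = [S.T @ coef_true + sigma * rng.standard_normal(n) for _ in range(N)]
        data = FunctionalDataset(list(range(N)), [t] * N, values, np.empty((N, 0)))
        cfg = ModelConfig(K=1, P=5, M=0, R=0, order=3, n_iter=1500, burn_in=300)
        d = run_mcmc(data, cfg, seed=4, basis=basis)
        post_mean_curve = (d.draws["v"][:, 0, :] @ S).mean(axis=0)
        # analytic posterior mean averaged over the sampled (sigma2, tau) pairs
        pen = make_penalty(5)
        ref = np.zeros(n)
        Sy = sum(S @ y for y in values)
        for j in range(d.n_draws):
            prec = N * (S @ S.T) / d.draws["sigma2"][j] + d.draws["tau_v"][j][0] * pen.DtD
            ref += S.T @ np.linalg.solve(prec, Sy / d.draws["sigma2"][j])
        ref /= d.n_draws
        assert np.max(np.abs(post_mean_curve - ref)) < 0.05
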