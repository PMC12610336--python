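import numpy as np
import pytest
from scipy.special import gammaln, logsumexp
from scipy.stats import multivariate_normal

from fmmm.basis import eval_design, make_basis, make_penalty
from fmmm.model_core import (
    DesignCache,
    Hyperparameters,
    ModelConfig,
    ParameterState,
    allocation_design_matrix,
    conditional_loglik,
    covariance_surface,
    log_prior,
    marginal_loglik,
    mean_function,
)
from fmmm.sampler import draw_prior_state, simulate_observations

from conftest import make_tiny_dataset


class TestHyperparameters:
    def test_defaults_valid(self):
        Hyperparameters()

    def test_shrinkage_ordering_required(self):
        with pytest.raises(ValueError, match="alpha_2 > beta_2"):
            Hyperparameters(alpha_2=1.0, beta_2=2.0)

    def test_positivity_required(self):
        with pytest.raises(ValueError, match="must be > 0"):
            Hyperparameters(nu_gamma=0.0)


class TestMeanFunction:
    def setup_method(self):
        self.basis = make_basis((0.0, 1.0), P=6, order=4)
        self.state = ParameterState.zeros(K=2, P=6, M=1, R=1, N=3)
        self.t = np.linspace(0, 1, 11)

    def test_zero_coefficients_zero_function(self):
        out = mean_function(self.state, 0, np.array([0.3]), self.t, self.basis)
        np.testing.assert_array_equal(out, np.zeros(11))

    def test_constant_coefficients_constant_function(self):
        self.state.v[1] = 2.5
        out = mean_function(self.state, 1, np.array([0.0]), self.t, self.basis)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_affine_in_x_at_fixed_t(self, rng):
        self.state.v[0] = rng.standard_normal(6)
        self.state.eta[0, :, 0] = rng.standard_normal(6)
        f = lambda x: mean_function(self.state, 0, np.array([x]), self.t, self.basis)
        np.testing.assert_allclose(f(0.0), (f(-1.0) + f(1.0)) / 2, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="expected R=1"):
            mean_function(self.state, 0, np.array([1.0, 2.0]), self.t, self.basis)


class TestCovarianceSurface:
    def test_zero_loadings_zero_surface(self):
        basis = make_basis((0.0, 1.0), P=5, order=3)
        state = ParameterState.zeros(2, 5, 2, 0, 1)
        C = covariance_surface(state, 0, 0, np.linspace(0, 1, 7),
                               np.linspace(0, 1, 9), basis)
        assert C.shape == (7, 9)
        np.testing.assert_array_equal(C, 0.0)

    def test_rank_one_symmetric_psd(self, rng):
        basis = make_basis((0.0, 1.0), P=5, order=3)
        state = ParameterState.zeros(1, 5, 1, 0, 1)
        state.phi[0, :, 0] = rng.standard_normal(5)
        g = np.linspace(0, 1, 21)
        C = covariance_surface(state, 0, 0, g, g, basis)
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.linalg.matrix_rank(C, tol=1e-10) == 1
        assert np.min(np.linalg.eigvalsh((C + C.T) / 2)) > -1e-10

    def test_transpose_symmetry_across_features(self, rng):
        basis = make_basis((0.0, 1.0), P=5, order=3)
        state = ParameterState.zeros(2, 5, 2, 0, 1)
        state.phi = rng.standard_normal(state.phi.shape)
        s, t = rng.uniform(0, 1, 6), rng.uniform(0, 1, 8)
        C01 = covariance_surface(state, 0, 1, s, t, basis)
        C10 = covariance_surface(state, 1, 0, t, s, basis)
        np.testing.assert_allclose(C01, C10.T, atol=1e-12)


class TestConditionalLoglik:
    def test_zero_residuals_special_variance(self, rng):
        # residuals exactly 0 and sigma2 = 1/(2 pi) make the log-density vanish
        state, data, basis, _ = make_tiny_dataset(rng, N=2, n=4, sigma2=0.0)
        state.sigma2 = 1.0 / (2 * np.pi)
        assert conditional_loglik(state, data, basis) == pytest.approx(0.0, abs=1e-9)

    def test_single_feature_matches_direct_formula(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=3, n=6, K=1, M=1, R=0)
        ll = conditional_loglik(state, data, basis)
        direct = 0.0
        for i in range(3):
            S = eval_design(basis, data.times[i])
            mu = S.T @ (state.v[0] + state.phi[0, :, 0] * state.chi[i, 0])
            r = data.values[i] - mu
            n = r.size
            direct += -0.5 * (n * np.log(2 * np.pi * state.sigma2)
                              + r @ r / state.sigma2)
        assert ll == pytest.approx(direct, rel=1e-12)

    def test_label_permutation_invariance(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=3, n=6, K=3, M=2, R=1)
        ll = conditional_loglik(state, data, basis)
        perm = np.array([2, 0, 1])
        state.v = state.v[perm]
        state.eta = state.eta[perm]
        state.phi = state.phi[perm]
        state.Z = state.Z[:, perm]
        state.pi = state.pi[perm]
        assert conditional_loglik(state, data, basis) == pytest.approx(ll, rel=1e-12)

    def test_nonpositive_variance_rejected(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng)
        state.sigma2 = 0.0
        with pytest.raises(ValueError):
            conditional_loglik(state, data, basis)


class TestMarginalLoglik:
    def test_zero_loadings_reduces_to_conditional(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=2, n=5, M=1)
        state.phi[...] = 0.0
        state.chi[...] = 0.0
        assert marginal_loglik(state, data, basis) == pytest.approx(
            conditional_loglik(state, data, basis), rel=1e-12
        )

    def test_matches_dense_gaussian_oracle(self, rng):
        """Score marginalization equals the brute-force linear-Gaussian
        integral on the tiny N=1, n=3, P=3, M=1, K=2 instance."""
        state, data, basis, _ = make_tiny_dataset(rng, N=1, n=3, P=3, M=1, K=2)
        S = eval_design(basis, data.times[0])
        theta = np.einsum("k,kpm->pm", state.Z[0], state.phi)
        A = S.T @ theta
        mu = S.T @ (state.Z[0] @ state.v + state.Z[0] @ (state.eta @ data.covariates[0]))
        cov = state.sigma2 * np.eye(3) + A @ A.T
        oracle = multivariate_normal(mu, cov).logpdf(data.values[0])
        assert marginal_loglik(state, data, basis) == pytest.approx(oracle, abs=1e-8)

    def test_matches_monte_carlo_over_scores(self, rng):
        state, data, basis, _ = make_tiny_dataset(rng, N=1, n=3, P=3, M=1, K=2)
        cache = DesignCache(data, basis)
        n_mc = 100_000
        mc_rng = np.random.default_rng(99)
        lls = np.empty(n_mc)
        work = state.copy()
        for s in range(n_mc):
            work.chi = mc_rng.standard_normal((1, 1))
            lls[s] = conditional_loglik(work, data, basis, cache=cache)
        est = logsumexp(lls) - np.log(n_mc)
        # MC standard error of log-mean-exp via delta method
        w = np.exp(lls - lls.max())
        se = np.std(w) / (np.mean(w) * np.sqrt(n_mc))
        assert abs(est - marginal_loglik(state, data, basis)) < 3 * se


class TestLogPrior:
    def test_constant_mean_coefficients_zero_penalty(self, rng):
        pen = make_penalty(4)
        hyper = Hyperparameters()
        cfg = ModelConfig(K=1, P=4, M=0, R=0, ridge=0.0)
        st = ParameterState.zeros(1, 4, 0, 0, 1)
        st.v[0] = 5.0
        base = log_prior(st, hyper, pen)
        st2 = st.copy()
        st2.v[0] = -11.0  # any constant: RW1 exponent identically 0
        assert log_prior(st2, hyper, pen) == pytest.approx(base, rel=1e-12)

    def test_dirichlet_term_matches_hand_coded_density(self, rng):
        K, N = 3, 4
        pen = make_penalty(4)
        hyper = Hyperparameters()
        st = ParameterState.zeros(K, 4, 0, 0, N)
        st.alpha3 = 2.4
        base = log_prior(st, hyper, pen)
        z = np.array([0.5, 0.3, 0.2])
        st2 = st.copy()
        st2.Z[0] = z
        alpha = st.alpha3 * st.pi
        hand = (
            gammaln(alpha.sum()) - gammaln(alpha).sum()
            + np.sum((alpha - 1) * np.log(z))
        )
        uniform = (
            gammaln(alpha.sum()) - gammaln(alpha).sum()
            + np.sum((alpha - 1) * np.log(np.full(K, 1 / 3)))
        )
        assert log_prior(st2, hyper, pen) - base == pytest.approx(
            hand - uniform, rel=1e-10
        )

    def test_mgp_cumulative_precision_increases_in_m(self):
        """Monte-Carlo check that E[tau~_mk] increases with m when
        alpha_2 > beta_2 (so loading variances shrink with m)."""
        rng = np.random.default_rng(7)
        n = 100_000
        a1 = rng.gamma(2.0, size=n) / 1.0
        a2 = rng.gamma(3.0, size=n) / 1.0
        d1 = rng.gamma(np.maximum(a1, 1e-12))
        d2 = rng.gamma(np.maximum(a2, 1e-12))
        d3 = rng.gamma(np.maximum(a2, 1e-12))
        tau1, tau2, tau3 = d1, d1 * d2, d1 * d2 * d3
        assert tau1.mean() < tau2.mean() < tau3.mean()

    def test_out_of_support_is_minus_inf_not_exception(self, rng):
        pen = make_penalty(3)
        hyper = Hyperparameters()
        st = ParameterState.zeros(2, 3, 1, 0, 2)
        st.sigma2 = -1.0
        assert log_prior(st, hyper, pen) == -np.inf
        st = ParameterState.zeros(2, 3, 1, 0, 2)
        st.Z[0] = [1.0, 0.0]  # boundary of the open simplex
        assert log_prior(st, hyper, pen) == -np.inf

    def test_finite_on_interior_prior_draw(self, rng):
        cfg = ModelConfig(K=2, P=4, M=2, R=1, ridge=2.0)
        st = draw_prior_state(cfg, N=3, rng=rng)
        pen = make_penalty(4)
        val = log_prior(st, cfg.hyper, pen, ridge=2.0)
        assert np.isfinite(val)


class TestAllocationDesignMatrix:
    def test_vertex_row(self):
        C, rank, ok = allocation_design_matrix(np.array([[1.0, 0.0]]))
        np.testing.assert_array_equal(C[0], [1.0, 0.0, 0.0])

    def test_rows_sum_to_one(self, rng):
        Z = rng.dirichlet(np.ones(3), size=8)
        C, _, _ = allocation_design_matrix(Z)
        np.testing.assert_allclose(C.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_rows_rank_one(self):
        Z = np.tile([0.3, 0.7], (10, 1))
        C, rank, ok = allocation_design_matrix(Z)
        assert rank == 1
        assert not ok

    def test_scattered_rows_full_rank(self, rng):
        Z = rng.dirichlet(np.ones(2), size=20)
        Z[0] = [1, 0]
        Z[1] = [0, 1]
        _, rank, ok = allocation_design_matrix(Z)
        assert rank == 3
        assert ok
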