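import numpy as np
import pytest

from fmmm.basis import make_basis, make_penalty
from fmmm.model_core import Hyperparameters, ModelConfig, ParameterState
from fmmm.sampler import draw_prior_state, geweke_test, simulate_observations


@pytest.fixture(scope="session")
def geweke_report():
    """Geweke joint-distribution test report on the tiny model, computed once
    per session (used by the sampler-correctness and acceptance tests)."""
    hyper = Hyperparameters(alpha_0=5.0, beta_0=4.0)
    cfg = ModelConfig(
        K=2, P=4, M=1, R=0, ridge=4.0, hyper=hyper,
        kappa_alloc=10.0, step_a=0.5, step_pi=0.5, step_alpha3=0.5,
    )
    return geweke_test(cfg, N=4, n_points=6, n_draws=10_000, seed=2024,
                       thin_successive=3)


@pytest.fixture(scope="session")
def allocation_tv():
    """Total-variation distances between the allocation MH chain's stationary
    marginals and the brute-force 201-cell grid posterior on the two-curve toy
    (computed once per session)."""
    from fmmm.model_core import DesignCache
    from fmmm.sampler import update_allocations

    rng = np.random.default_rng(2024)
    state, data, basis, _ = make_tiny_dataset(
        rng, N=2, n=10, K=2, P=4, M=1, R=0, order=4, sigma2=0.05
    )
    state.sigma2 = 0.05
    state.alpha3 = 3.0
    state.pi = np.array([0.5, 0.5])
    cache = DesignCache(data, basis)
    alpha = state.alpha3 * state.pi

    from fmmm.model_core import marginal_loglik_curve

    n_grid = 201
    edges = np.linspace(0.0, 1.0, n_grid + 1)
    mid = (edges[:-1] + edges[1:]) / 2
    exact = []
    for i in range(2):
        logp = np.array([
            marginal_loglik_curve(state, cache, i, z=np.array([z1, 1 - z1]))
            + (alpha[0] - 1) * np.log(z1) + (alpha[1] - 1) * np.log(1 - z1)
            for z1 in mid
        ])
        p = np.exp(logp - logp.max())
        exact.append(p / p.sum())

    # pilot adaptation of the proposal concentration (larger kappa = tighter
    # proposals = higher acceptance), then a long frozen chain
    kappa = 40.0
    for _ in range(50):
        _, acc = update_allocations(state, cache, rng, kappa=kappa)
        kappa = float(np.clip(
            kappa * (1.4 if acc < 0.25 else 0.7 if acc > 0.5 else 1.0),
            2.0, 500.0,
        ))
    n_sweeps = 400_000
    counts = np.zeros((2, n_grid))
    for _ in range(n_sweeps):
        update_allocations(state, cache, rng, kappa=kappa)
        for i in range(2):
            counts[i, min(int(state.Z[i, 0] * n_grid), n_grid - 1)] += 1
    return [
        0.5 * float(np.abs(counts[i] / counts[i].sum() - exact[i]).sum())
        for i in range(2)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cubic_basis():
    return make_basis((0.0, 1.0), P=8, order=4)


@pytest.fixture
def penalty8():
    return make_penalty(8)


@pytest.fixture
def tiny_state(rng):
    """A small valid parameter state (K=2, P=3, M=1, R=1, N=2)."""
    cfg = ModelConfig(K=2, P=3, M=1, R=1, order=3, ridge=1.0)
    return draw_prior_state(cfg, N=2, rng=rng)


def make_tiny_dataset(rng, N=2, n=5, K=2, P=3, M=1, R=1, order=3, sigma2=0.1):
    """Simulate a tiny coherent (state, dataset, basis, config) tuple."""
    cfg = ModelConfig(K=K, P=P, M=M, R=R, order=order, ridge=1.0)
    state = draw_prior_state(cfg, N=N, rng=rng)
    state.sigma2 = sigma2
    basis = make_basis((0.0, 1.0), P, order)
    times = [np.linspace(0.0, 1.0, n)] * N
    X = rng.standard_normal((N, R)) if R else np.empty((N, 0))
    data = simulate_observations(state, times, X, basis, rng)
    return state, data, basis, cfg
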