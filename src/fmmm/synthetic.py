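"""Synthetic data from the model's own generative process, and the scenario
grids of the two simulation studies (structure recovery and K selection).

Curves are generated exactly as the sampling model states: allocations from
the hierarchical Dirichlet, standard-normal factor scores, feature means
linear in standardized covariates, pseudo-eigenfunction covariance, iid
Gaussian noise on a regular time grid.  Study truths are drawn once from the
prior stack under a frozen master seed, subject to two structural conditions
that the identifiability theory requires of a usable truth: one pure anchor
observation per feature (separability) and feature mean curves that are not
mutually degenerate (minimum pairwise L2 separation, enforced by redrawing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSystem, eval_design, make_basis
from .functional_data import FunctionalDataset, standardize_covariates
from .model_core import ModelConfig, ParameterState
from .sampler import draw_prior_state, simulate_observations

__all__ = [
    "TruthBundle",
    "simulate_dataset",
    "draw_study_truth",
    "study1_scenarios",
    "study2_scenario",
]

#: master seed freezing the study truth parameters
MASTER_TRUTH_SEED = 20_240_612

#: generator defaults: noise variance, allocation concentration, domain
DEFAULT_SIGMA2 = 0.05
DEFAULT_ALLOC_CONC = 1.5
DOMAIN = (0.0, 1.0)

#: minimum pairwise L2 distance between feature mean curves in a usable truth
MIN_FEATURE_SEPARATION = 1.0

#: within-feature process scale: sqrt of the covariance trace of each feature,
#: as a fraction of the smallest pairwise feature separation
COV_SCALE = 0.3


@dataclass
class TruthBundle:
    """Ground truth of a simulated dataset: the generating parameters
    (restricted to v, eta, phi, Z, sigma2), the config, and the seed."""

    state: ParameterState
    config: ModelConfig
    basis: BasisSystem
    seed: int

    def mean_fn(self, k: int):
        """True feature-k mean as a callable f(t) (R=0) or f(x, t)."""
        from .model_core import mean_function

        if self.config.R == 0:
            return lambda t: mean_function(self.state, k, None, t, self.basis)
        return lambda x, t: mean_function(
            self.state, k, np.atleast_1d(x), t, self.basis
        )

    def marginal_mean_fn(self, k: int):
        """Feature-k mean at the covariate center x = 0, i.e. v_k' B(t)."""
        S_fn = lambda t: eval_design(self.basis, t)
        return lambda t: S_fn(t).T @ self.state.v[k]


def _feature_separation(state: ParameterState, basis: BasisSystem) -> float:
    grid = np.linspace(basis.domain[0], basis.domain[1], 101)
    S = eval_design(basis, grid)
    curves = state.v @ S  # K x G
    dists = []
    for a in range(state.K):
        for b in range(a + 1, state.K):
            d2 = np.trapezoid((curves[a] - curves[b]) ** 2, grid)
            dists.append(np.sqrt(d2))
    return float(min(dists)) if dists else np.inf


def draw_study_truth(
    config: ModelConfig,
    seed: int = MASTER_TRUTH_SEED,
    sigma2: float = DEFAULT_SIGMA2,
    cov_scale: float = COV_SCALE,
    max_tries: int = 200,
) -> tuple[ParameterState, BasisSystem]:
    """Draw frozen truth parameters (v, eta, phi, sigma2) from the priors.

    Two structural normalizations make the draw a usable study target.
    First, feature mean curves must be pairwise separated by at least
    ``MIN_FEATURE_SEPARATION`` in L2 (enforced by per-feature redrawing); an
    unseparated truth is practically unidentifiable.  Second, each feature's
    pseudo-eigenfunction loadings are rescaled so the square root of its
    covariance trace equals ``cov_scale`` times the smallest separation: the
    MGP prior alone puts no scale hierarchy on the draws, whereas recoverable
    mixed membership structure requires within-feature functional variation
    smaller than the between-feature mean differences (as in the motivating
    EEG features).  The prior draw requires a proper prior on v, so a unit
    ridge is used for generation.
    """
    gen_cfg = ModelConfig(
        K=config.K, P=config.P, M=config.M, R=config.R, order=config.order,
        hyper=config.hyper, ridge=1.0,
    )
    basis = make_basis(DOMAIN, config.P, config.order)
    grid = np.linspace(basis.domain[0], basis.domain[1], 101)
    S = eval_design(basis, grid)
    rng = np.random.default_rng(seed)
    truth = draw_prior_state(gen_cfg, N=1, rng=rng)
    w_grid = np.empty(grid.size)
    w_grid[0] = (grid[1] - grid[0]) / 2
    w_grid[-1] = (grid[-1] - grid[-2]) / 2
    w_grid[1:-1] = (grid[2:] - grid[:-2]) / 2

    def _dist_to_affine_span(curve: np.ndarray, others: np.ndarray) -> float:
        """Weighted-L2 distance from `curve` to the affine hull of `others`."""
        base = others[0]
        diff = curve - base
        directions = others[1:] - base  # (k-1) x G
        if directions.shape[0]:
            sw = np.sqrt(w_grid)
            Q, _ = np.linalg.qr((directions * sw).T)
            d = diff * sw - Q @ (Q.T @ (diff * sw))
            return float(np.sqrt(d @ d))
        return float(np.sqrt(np.sum(w_grid * diff**2)))

    # sequential per-feature rejection: redraw feature k's mean coefficients
    # until its curve is separated from the affine hull of those already
    # accepted — pairwise distance alone permits nearly collinear features,
    # which a (k-1)-feature mixture could reproduce (unidentifiable K)
    for k in range(1, config.K):
        curves = truth.v @ S  # K x G
        for attempt in range(max_tries):
            if _dist_to_affine_span(curves[k], curves[:k]) >= MIN_FEATURE_SEPARATION:
                break
            fresh = draw_prior_state(gen_cfg, N=1, rng=rng)
            truth.v[k] = fresh.v[k]
            truth.tau_v[k] = fresh.tau_v[k]
            curves[k] = truth.v[k] @ S
        else:
            raise RuntimeError(
                "could not draw a separated truth; check configuration"
            )
    sep = _feature_separation(truth, basis)
    if config.M > 0 and cov_scale > 0 and np.isfinite(sep):
        w = np.gradient(grid)
        for k in range(config.K):
            # covariance trace on the grid: int sum_m (phi_km' B(t))^2 dt
            curves = truth.phi[k].T @ S  # M x G
            trace = float(np.sum(w * (curves**2).sum(axis=0)))
            if trace > 0:
                truth.phi[k] *= cov_scale * sep / np.sqrt(trace)
    truth.sigma2 = sigma2
    return truth, basis


def simulate_dataset(
    config: ModelConfig,
    n_curves: int,
    n_points: int,
    seed: int,
    truth: ParameterState | None = None,
    basis: BasisSystem | None = None,
    sigma2: float = DEFAULT_SIGMA2,
    alloc_conc: float = DEFAULT_ALLOC_CONC,
    anchor_per_feature: bool = True,
) -> tuple[FunctionalDataset, TruthBundle]:
    """Generate a dataset from the model's own sampling structure.

    Covariates are drawn standard normal and standardized; allocations
    z_i ~ Dir(alloc_conc * 1); factor scores chi_im ~ N(0,1); observations on
    a regular grid of ``n_points`` with N(0, sigma2) noise.  When ``truth`` is
    None the feature parameters are drawn from the priors (separation
    enforced); when given, only (z, chi, x, noise) are redrawn, so repeated
    calls share the same features.  ``anchor_per_feature`` plants one pure
    observation per feature, making the separability condition hold by
    construction.
    """
    rng = np.random.default_rng(seed)
    if basis is None:
        basis = make_basis(DOMAIN, config.P, config.order)
    if truth is None:
        truth, basis = draw_study_truth(config, seed=seed, sigma2=sigma2)

    K, R, M = config.K, config.R, config.M
    N = n_curves
    state = truth.copy()
    state.sigma2 = truth.sigma2 if truth.sigma2 > 0 else sigma2

    if R > 0:
        X = standardize_covariates(rng.standard_normal((N, R))).X_std
    else:
        X = np.empty((N, 0))
    if K > 1:
        Z = rng.dirichlet(np.full(K, alloc_conc), size=N)
        if anchor_per_feature and N >= K:
            for k in range(K):
                Z[k] = np.eye(K)[k]
    else:
        Z = np.ones((N, 1))
    chi = rng.standard_normal((N, M))
    state.Z = Z
    state.chi = chi

    times = [np.linspace(DOMAIN[0], DOMAIN[1], n_points)] * N
    dataset = simulate_observations(state, times, X, basis, rng)
    bundle = TruthBundle(state=state, config=config, basis=basis, seed=seed)
    return dataset, bundle


def study1_scenarios(
    base_config: ModelConfig | None = None,
    sample_sizes: tuple[int, int, int] = (40, 80, 160),
    n_replicates: int = 50,
    n_points: int = 25,
    seed: int = MASTER_TRUTH_SEED,
) -> list[dict]:
    """Scenario grid of the structure-recovery study.

    Nine generation scenarios: R in {0, 1, 2} crossed with three sample sizes,
    each K=2 and ``n_points`` regular-grid observations per curve.  Each
    scenario lists its fit specs: the correctly specified fit plus the stated
    misspecified fit (data with R=1 fit without the covariate; data with R=0
    fit with one randomly generated covariate), and per-replicate seeds.
    """
    base_config = base_config or ModelConfig(K=2, P=8, M=2)
    scenarios = []
    ss = np.random.SeedSequence(seed)
    for R in (0, 1, 2):
        for N in sample_sizes:
            child = ss.spawn(1)[0]
            rep_seeds = [int(s.generate_state(1)[0] % 2**31)
                         for s in child.spawn(n_replicates)]
            fits = [{"name": "correct", "R_fit": R, "random_covariate": False}]
            if R == 1:
                fits.append({"name": "underspecified", "R_fit": 0,
                             "random_covariate": False})
            if R == 0:
                fits.append({"name": "overspecified", "R_fit": 1,
                             "random_covariate": True})
            scenarios.append({
                "R": R,
                "N": N,
                "K": base_config.K,
                "P": base_config.P,
                "M": base_config.M,
                "n_points": n_points,
                "replicate_seeds": rep_seeds,
                "fits": fits,
            })
    assert len(scenarios) == 9
    return scenarios


def study2_scenario(
    base_config: ModelConfig | None = None,
    n_datasets: int = 50,
    N: int = 120,
    n_points: int = 25,
    seed: int = MASTER_TRUTH_SEED,
    K_fits: tuple[int, ...] = (2, 3, 4, 5),
) -> dict:
    """Scenario of the K-selection study: ``n_datasets`` datasets from one
    frozen K=3, R=1 truth, each fit with K in {2, 3, 4, 5}.

    All datasets share the same truth parameters and differ only in the
    (z, chi, x, noise) seeds.
    """
    base_config = base_config or ModelConfig(K=3, P=8, M=3, R=1)
    if base_config.K != 3 or base_config.R != 1:
        raise ValueError("the K-selection study generates from K=3, R=1")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_datasets)]
    return {
        "truth_seed": seed,
        "K_true": 3,
        "R": 1,
        "N": N,
        "P": base_config.P,
        "M": base_config.M,
        "n_points": n_points,
        "dataset_seeds": rep_seeds,
        "K_fits": list(K_fits),
    }
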