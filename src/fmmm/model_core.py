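"""Model parameters, likelihoods and priors of the covariate-adjusted
functional mixed membership model.

Each observed curve is a convex combination of K latent functional features.
Feature k has mean mu_k(x, t) = (v_k + eta_k x)' B(t), linear in the
standardized covariates x, and the joint covariance across features is
approximated by M pseudo-eigenfunctions phi_km' B(t).  Conditional on the
simplex-valued allocations z_i and standard-normal factor scores chi_im,

    Y_i(t_i) ~ N( sum_k Z_ik [ S_i'(v_k + eta_k x_i) + sum_m chi_im S_i' phi_km ],
                  sigma^2 I ),

with S_i the P x n_i basis design at the observation times.  Integrating the
scores out yields a dense Gaussian likelihood whose covariance is the rank-M
form V(t_i, z_i) + sigma^2 I with

    V = S_i' Theta_i Theta_i' S_i,   Theta_i = sum_k Z_ik phi_k  (P x M).

The prior stack comprises a multiplicative gamma process (MGP) on the
pseudo-eigenfunction coefficients, first-order random-walk (RW1) smoothing on
the mean coefficients, a hierarchical Dirichlet prior on the allocations, and
an inverse-gamma prior on the noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .basis import BasisSystem, PenaltyOperator, eval_design
from .functional_data import FunctionalDataset

__all__ = [
    "Hyperparameters",
    "ParameterState",
    "ModelConfig",
    "DesignCache",
    "mean_function",
    "covariance_surface",
    "conditional_loglik",
    "marginal_loglik",
    "marginal_loglik_curve",
    "log_prior",
    "allocation_design_matrix",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Prior hyperparameters; all strictly positive, with alpha_2 > beta_2 so
    the expected MGP cumulative precisions increase with the eigen index
    (stochastically shrinking higher-index loadings toward zero)."""

    nu_gamma: float = 3.0
    alpha_1: float = 2.0
    beta_1: float = 1.0
    alpha_2: float = 3.0
    beta_2: float = 1.0
    alpha_v: float = 1.0
    beta_v: float = 1.0
    alpha_eta: float = 1.0
    beta_eta: float = 1.0
    c_pi: float = 10.0  # symmetric Dirichlet base measure on pi
    b_alpha3: float = 1.0  # exponential rate on the Dirichlet concentration
    alpha_0: float = 1.0
    beta_0: float = 1.0

    def __post_init__(self) -> None:
        for name, val in self.__dict__.items():
            if not val > 0:
                raise ValueError(f"hyperparameter {name} must be > 0, got {val}")
        if not self.alpha_2 > self.beta_2:
            raise ValueError("need alpha_2 > beta_2 for increasing shrinkage in m")


@dataclass
class ModelConfig:
    """Model dimensions, priors, and MCMC settings."""

    K: int = 2
    P: int = 8
    M: int = 2
    order: int = 4
    R: int = 0
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    # MCMC
    n_iter: int = 2000
    burn_in: int = 500
    thin: int = 1
    n_temps: int = 0  # ladder length L for tempered allocation sweeps; 0 = plain
    beta_min: float = 0.1  # coldest inverse temperature of the geometric ladder
    temper_interval: int = 5  # run a tempered sweep every this many iterations
    kappa_alloc: float = 50.0  # Dirichlet allocation-proposal concentration
    step_a: float = 0.3  # log-RW step for MGP shape parameters a1, a2
    step_pi: float = 0.3  # logistic-normal proposal scale for pi
    step_alpha3: float = 0.3  # log-RW step for alpha3
    ridge: float = 0.0  # optional proper Gaussian precision on v, eta (0 = RW1 only)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K >= 1 required")
        if not (0 <= self.M <= self.K * self.P):
            raise ValueError("require 0 <= M <= K*P")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")


@dataclass
class ParameterState:
    """One full draw of the model parameters.

    Shapes: v (K,P); eta (K,P,R); phi (K,P,M); chi (N,M); Z (N,K);
    gamma (K,P,M); delta (K,M); a1, a2, tau_v, pi (K,); tau_eta (K,R);
    sigma2, alpha3 scalars.
    """

    v: np.ndarray
    eta: np.ndarray
    phi: np.ndarray
    chi: np.ndarray
    Z: np.ndarray
    sigma2: float
    gamma: np.ndarray
    delta: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    tau_v: np.ndarray
    tau_eta: np.ndarray
    pi: np.ndarray
    alpha3: float

    @property
    def K(self) -> int:
        return self.v.shape[0]

    @property
    def P(self) -> int:
        return self.v.shape[1]

    @property
    def M(self) -> int:
        return self.phi.shape[2]

    @property
    def R(self) -> int:
        return self.eta.shape[2]

    @property
    def N(self) -> int:
        return self.Z.shape[0]

    def tau_tilde(self) -> np.ndarray:
        """Cumulative MGP precisions tau~_mk = prod_{n<=m} delta_nk, shape (K, M)."""
        return np.cumprod(self.delta, axis=1)

    def copy(self) -> "ParameterState":
        return ParameterState(
            **{
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
            }
        )

    def validate(self, atol: float = 1e-8) -> None:
        if not np.all(np.isfinite(self.Z)) or np.any(self.Z < -atol) or np.any(self.Z > 1 + atol):
            raise ValueError("allocations must lie in [0, 1]")
        if not np.allclose(self.Z.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("allocation rows must sum to 1")
        if not np.allclose(self.pi.sum(), 1.0, atol=1e-10) or np.any(self.pi < 0):
            raise ValueError("pi must lie on the simplex")
        for name in ("sigma2", "alpha3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gamma", "delta", "a1", "a2", "tau_v", "tau_eta"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} entries must be positive")

    @staticmethod
    def zeros(K: int, P: int, M: int, R: int, N: int) -> "ParameterState":
        return ParameterState(
            v=np.zeros((K, P)),
            eta=np.zeros((K, P, R)),
            phi=np.zeros((K, P, M)),
            chi=np.zeros((N, M)),
            Z=np.full((N, K), 1.0 / K),
            sigma2=1.0,
            gamma=np.ones((K, P, M)),
            delta=np.ones((K, M)),
            a1=np.ones(K),
            a2=np.ones(K),
            tau_v=np.ones(K),
            tau_eta=np.ones((K, R)),
            pi=np.full(K, 1.0 / K),
            alpha3=1.0,
        )


class DesignCache:
    """Per-curve basis design matrices and cross-products, computed once."""

    def __init__(self, dataset: FunctionalDataset, basis: BasisSystem):
        self.dataset = dataset
        self.basis = basis
        # curves often share one observation grid; evaluate each distinct grid once
        grid_keys: dict[bytes, int] = {}
        self.grid_of = np.empty(dataset.n_curves, dtype=int)
        unique_S: list[np.ndarray] = []
        for i, t in enumerate(dataset.times):
            key = t.tobytes()
            if key not in grid_keys:
                grid_keys[key] = len(unique_S)
                unique_S.append(eval_design(basis, t))
            self.grid_of[i] = grid_keys[key]
        self.unique_S = unique_S
        self.S = [unique_S[g] for g in self.grid_of]  # P x n_i views
        unique_SSt = [s @ s.T for s in unique_S]
        self.SSt = [unique_SSt[g] for g in self.grid_of]  # P x P
        self.Sy = [s @ y for s, y in zip(self.S, dataset.values)]
        self.X = dataset.covariates
        self.n_total = int(sum(dataset.n_points))
        # per-grid curve groups with stacked data, for vectorized updates
        self.groups = []
        for g, S in enumerate(unique_S):
            idx = np.where(self.grid_of == g)[0]
            Y = np.stack([dataset.values[i] for i in idx])  # |idx| x n_g
            self.groups.append(
                {"idx": idx, "S": S, "SSt": unique_SSt[g], "Y": Y,
                 "Sy": Y @ S.T}  # |idx| x P
            )

    @property
    def N(self) -> int:
        return self.dataset.n_curves


# ---------------------------------------------------------------------------
# mean / covariance structure


def mean_function(
    state: ParameterState,
    k: int,
    x: np.ndarray | None,
    times: np.ndarray,
    basis: BasisSystem,
) -> np.ndarray:
    """Feature-k mean mu_k(x, t) = (v_k + eta_k x)' B(t) at the given times."""
    S = eval_design(basis, times)
    coef = state.v[k].copy()
    if state.R > 0:
        if x is None:
            raise ValueError("covariate vector x required when R > 0")
        x = np.asarray(x, dtype=float).ravel()
        if x.size != state.R:
            raise ValueError(f"x has length {x.size}, expected R={state.R}")
        coef = coef + state.eta[k] @ x
    return S.T @ coef


def covariance_surface(
    state: ParameterState,
    k: int,
    k2: int,
    s_times: np.ndarray,
    t_times: np.ndarray,
    basis: BasisSystem,
) -> np.ndarray:
    """Cross-covariance C_{k,k'}(s, t) = B(s)' [sum_m phi_km phi_k'm'] B(t)."""
    Ss = eval_design(basis, s_times)
    St = eval_design(basis, t_times)
    core = state.phi[k] @ state.phi[k2].T  # P x P
    return Ss.T @ core @ St


def _combined_mean_coef(state: ParameterState, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """sum_k Z_k (v_k + eta_k x), shape (P,)."""
    coef = z @ state.v
    if state.R > 0:
        coef = coef + z @ (state.eta @ x)
    return coef


def conditional_loglik(
    state: ParameterState, dataset: FunctionalDataset, basis: BasisSystem,
    cache: DesignCache | None = None,
) -> float:
    """Gaussian log-likelihood conditional on the factor scores chi."""
    if not state.sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    cache = cache or DesignCache(dataset, basis)
    total = 0.0
    log2pi = np.log(2 * np.pi)
    for i in range(cache.N):
        x = cache.X[i]
        coef = _combined_mean_coef(state, x, state.Z[i])
        if state.M > 0:
            theta = np.einsum("k,kpm->pm", state.Z[i], state.phi)
            coef = coef + theta @ state.chi[i]
        resid = dataset.values[i] - cache.S[i].T @ coef
        n = resid.size
        total += -0.5 * (n * (log2pi + np.log(state.sigma2)) + resid @ resid / state.sigma2)
    return float(total)


def marginal_loglik_curve(
    state: ParameterState,
    cache: DesignCache,
    i: int,
    z: np.ndarray | None = None,
) -> float:
    """Score-marginalized Gaussian log-density of curve i (optionally at a
    trial allocation ``z``), computed through a Cholesky factorization of the
    M x M capacitance matrix (matrix inversion / determinant lemma)."""
    z = state.Z[i] if z is None else z
    x = cache.X[i]
    S = cache.S[i]
    y = cache.dataset.values[i]
    mu = S.T @ _combined_mean_coef(state, x, z)
    r = y - mu
    n = r.size
    s2 = state.sigma2
    log2pi = np.log(2 * np.pi)
    if state.M == 0:
        return float(-0.5 * (n * (log2pi + np.log(s2)) + r @ r / s2))
    theta = np.tensordot(z, state.phi, axes=(0, 0))  # P x M
    A = S.T @ theta  # n x M
    cap = s2 * np.eye(state.M) + A.T @ A
    try:
        L = np.linalg.cholesky(cap)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(cap) / state.M
        try:
            L = np.linalg.cholesky(cap + jitter * np.eye(state.M))
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                f"curve {i}: marginal covariance not PD even after jitter "
                f"{jitter:.3e} (sigma2={s2:.3e}, ||A||={np.linalg.norm(A):.3e})"
            ) from err
    # log|sigma2 I + A A'| = (n - M) log sigma2 + log|cap|
    logdet = (n - state.M) * np.log(s2) + 2.0 * np.sum(np.log(np.diag(L)))
    Atr = A.T @ r
    w = np.linalg.solve(L, Atr)
    quad = (r @ r - w @ w) / s2
    return float(-0.5 * (n * log2pi + logdet + quad))


def marginal_loglik(
    state: ParameterState, dataset: FunctionalDataset, basis: BasisSystem,
    cache: DesignCache | None = None,
) -> float:
    """Log-likelihood with the factor scores integrated out analytically."""
    if not state.sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    cache = cache or DesignCache(dataset, basis)
    return float(sum(marginal_loglik_curve(state, cache, i) for i in range(cache.N)))


# ---------------------------------------------------------------------------
# priors


def _gamma_logpdf(x: np.ndarray, shape: np.ndarray, rate: np.ndarray) -> np.ndarray:
    return shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + np.sum((alpha - 1) * np.log(x))
    )


def log_prior(
    state: ParameterState,
    hyper: Hyperparameters,
    penalty: PenaltyOperator,
    ridge: float = 0.0,
) -> float:
    """Joint log-prior of the full parameter stack.

    Proper components (MGP normals and gammas, Dirichlets, exponential,
    inverse-gamma) include their normalizing constants.  The RW1 smoothing
    priors on v_k and the columns of eta_k are improper; their contribution is
    -(tau/2)||D v||^2 plus the tau-dependent factor ((P-1)/2) log tau, which is
    exactly what the conjugate tau updates require.  An optional ridge term
    adds a proper N(0, ridge^{-1} I) factor on v and eta.  Out-of-support
    states return -inf rather than raising.
    """
    pos = [state.sigma2, state.alpha3]
    for arr in (state.gamma, state.delta, state.a1, state.a2, state.tau_v, state.tau_eta):
        pos.append(np.min(arr) if np.asarray(arr).size else 1.0)
    if min(pos) <= 0:
        return -np.inf
    if state.K > 1:
        if np.any(state.Z <= 0) or np.any(state.Z >= 1):
            return -np.inf  # Dirichlet support is the open simplex
        if np.any(state.pi <= 0) or not np.isclose(state.pi.sum(), 1.0, atol=1e-9):
            return -np.inf
        if not np.allclose(state.Z.sum(axis=1), 1.0, atol=1e-9):
            return -np.inf

    hp = hyper
    total = 0.0
    K, P, M, R = state.K, state.P, state.M, state.R
    log2pi = np.log(2 * np.pi)

    if M > 0:
        tau = state.tau_tilde()  # K x M
        prec = state.gamma * tau[:, None, :]  # K x P x M
        total += 0.5 * np.sum(np.log(prec) - log2pi - prec * state.phi**2)
        total += np.sum(_gamma_logpdf(state.gamma, hp.nu_gamma / 2, hp.nu_gamma / 2))
        total += np.sum(_gamma_logpdf(state.delta[:, 0], state.a1, np.ones(K)))
        if M > 1:
            total += np.sum(
                _gamma_logpdf(state.delta[:, 1:], state.a2[:, None], np.ones((K, M - 1)))
            )
    total += np.sum(_gamma_logpdf(state.a1, hp.alpha_1, hp.beta_1))
    total += np.sum(_gamma_logpdf(state.a2, hp.alpha_2, hp.beta_2))

    # RW1 smoothing: improper (tau-dependent part only) when ridge = 0, or the
    # proper Gaussian N(0, (tau D'D + ridge I)^{-1}) when a ridge anchor is set
    def _smooth_term(coef: np.ndarray, tau: float) -> float:
        q = penalty.quadratic_form(coef)
        if ridge <= 0:
            return 0.5 * (P - 1) * np.log(tau) - 0.5 * tau * q
        prec = tau * penalty.DtD + ridge * np.eye(P)
        _, logdet = np.linalg.slogdet(prec)
        return 0.5 * (logdet - P * log2pi) - 0.5 * (tau * q + ridge * coef @ coef)

    for k in range(K):
        total += _smooth_term(state.v[k], state.tau_v[k])
        for r in range(R):
            total += _smooth_term(state.eta[k, :, r], state.tau_eta[k, r])
    total += np.sum(_gamma_logpdf(state.tau_v, hp.alpha_v, hp.beta_v))
    if R > 0:
        total += np.sum(_gamma_logpdf(state.tau_eta, hp.alpha_eta, hp.beta_eta))

    # hierarchical Dirichlet on allocations (degenerate and omitted when K = 1)
    if K > 1:
        alpha_z = state.alpha3 * state.pi
        for i in range(state.N):
            total += _dirichlet_logpdf(state.Z[i], alpha_z)
        total += _dirichlet_logpdf(state.pi, np.full(K, hp.c_pi))
    total += np.log(hp.b_alpha3) - hp.b_alpha3 * state.alpha3

    # inverse-gamma noise
    total += (
        hp.alpha_0 * np.log(hp.beta_0)
        - gammaln(hp.alpha_0)
        - (hp.alpha_0 + 1) * np.log(state.sigma2)
        - hp.beta_0 / state.sigma2
    )
    return float(total)


def allocation_design_matrix(Z: np.ndarray) -> tuple[np.ndarray, int, bool]:
    """Quadratic allocation design C with rows
    (Z_i1^2, ..., Z_iK^2, 2 Z_i1 Z_i2, ..., 2 Z_i(K-1) Z_iK) and its rank.

    The identifiability of the covariance structure requires C to have full
    column rank K(K+1)/2, which in particular needs N >= K(K+1)/2 rows.
    """
    Z = np.asarray(Z, dtype=float)
    N, K = Z.shape
    cols = [Z[:, k] ** 2 for k in range(K)]
    for k in range(K):
        for k2 in range(k + 1, K):
            cols.append(2.0 * Z[:, k] * Z[:, k2])
    C = np.column_stack(cols)
    s = np.linalg.svd(C, compute_uv=False)
    rank = int(np.sum(s > 1e-8 * s[0])) if s.size else 0
    q = K * (K + 1) // 2
    return C, rank, bool(N >= q and rank == q)
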