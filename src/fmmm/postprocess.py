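"""Post-processing of posterior draws: label alignment, separability
rescaling, covariance eigen-analysis, and posterior summaries.

Mixed membership posteriors are invariant under permutations of the feature
labels and, more subtly, under affine re-parameterizations of the allocation
simplex.  Both are resolved here by pure re-parameterizations that leave every
draw's marginal likelihood unchanged: :func:`relabel_draws` aligns labels to a
reference draw, and :func:`rescale_to_separability` (two-feature models only)
stretches the allocations so that each feature has at least one pure "anchor"
observation, the separability normalization under which the model is
identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisSystem, eval_design
from .sampler import PosteriorDraws

__all__ = [
    "EigenSummary",
    "relabel_draws",
    "rescale_to_separability",
    "covariance_eigen",
    "summarize",
]


@dataclass
class EigenSummary:
    """Per-draw eigenvalues and L2(grid)-orthonormal eigenfunctions of the
    reconstructed covariance surface."""

    grid: np.ndarray
    eigenvalues: np.ndarray  # (n_draws, n_grid), descending
    eigenfunctions: np.ndarray  # (n_draws, n_grid, n_grid) columns = functions
    which: str = "pooled"


def _mean_curves_at_origin(
    draws: PosteriorDraws, basis: BasisSystem, grid: np.ndarray, j: int
) -> np.ndarray:
    """Feature mean curves at x = 0 (i.e. v_k' B(t)) for draw j; (K, n_grid)."""
    S = eval_design(basis, grid)
    return draws.draws["v"][j] @ S


def relabel_draws(
    draws: PosteriorDraws,
    basis: BasisSystem,
    grid: np.ndarray | None = None,
    reference: int | None = None,
) -> PosteriorDraws:
    """Align feature labels across draws (label-switching fix).

    For each draw the permutation minimizing the summed L2 distance between
    its feature mean curves at x = 0 and those of a reference draw (by default
    the maximum marginal-likelihood draw, located via the stored trace when
    available) is applied simultaneously to v, eta, phi, Z columns and pi.
    """
    from scipy.optimize import linear_sum_assignment

    if grid is None:
        grid = np.linspace(basis.domain[0], basis.domain[1], 100)
    n_draws = draws.n_draws
    if reference is None:
        if draws.loglik_trace.size:
            kept = draws.loglik_trace[draws.config.burn_in :: draws.config.thin]
            reference = int(np.argmax(kept[:n_draws]))
        else:
            reference = 0
    ref_curves = _mean_curves_at_origin(draws, basis, grid, reference)

    out = {k: v.copy() for k, v in draws.draws.items()}
    K = draws.config.K
    for j in range(n_draws):
        cur = _mean_curves_at_origin(draws, basis, grid, j)
        # cost[a, b] = L2 distance between draw-j feature a and reference feature b
        cost = ((cur[:, None, :] - ref_curves[None, :, :]) ** 2).sum(axis=2)
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=int)
        perm[cols] = rows  # new label b takes old feature perm[b]
        if np.all(perm == np.arange(K)):
            continue
        out["v"][j] = out["v"][j][perm]
        out["eta"][j] = out["eta"][j][perm]
        out["phi"][j] = out["phi"][j][perm]
        out["gamma"][j] = out["gamma"][j][perm]
        out["delta"][j] = out["delta"][j][perm]
        out["a1"][j] = out["a1"][j][perm]
        out["a2"][j] = out["a2"][j][perm]
        out["tau_v"][j] = out["tau_v"][j][perm]
        out["tau_eta"][j] = out["tau_eta"][j][perm]
        out["Z"][j] = out["Z"][j][:, perm]
        out["pi"][j] = out["pi"][j][perm]
    return PosteriorDraws(
        draws=out, config=draws.config, seed=draws.seed,
        acceptance=dict(draws.acceptance), loglik_trace=draws.loglik_trace.copy(),
    )


def rescale_to_separability(draws: PosteriorDraws) -> PosteriorDraws:
    """Enforce the separability normalization on each draw (K = 2 only).

    Allocations are mapped affinely so that min_i Z'_i1 = 0 and
    max_i Z'_i1 = 1 (each feature acquires a pure anchor observation), and the
    feature blocks (v, eta, phi) receive the compensating linear mix so that
    sum_k Z_ik f(k) = sum_k Z'_ik f'(k) for every curve: the likelihood of
    every draw is exactly preserved.  Degenerate draws with all allocations
    equal are left untouched.
    """
    if draws.config.K != 2:
        raise ValueError("separability rescaling is implemented for K = 2 only")
    out = {k: v.copy() for k, v in draws.draws.items()}
    for j in range(draws.n_draws):
        z1 = out["Z"][j][:, 0]
        lo, hi = float(z1.min()), float(z1.max())
        if hi - lo < 1e-12:
            continue  # degenerate draw; flagged by leaving it untransformed
        z1_new = (z1 - lo) / (hi - lo)
        out["Z"][j] = np.column_stack([z1_new, 1.0 - z1_new])
        # Z_old = Z_new @ A with A = [[hi, 1-hi], [lo, 1-lo]]
        A = np.array([[hi, 1.0 - hi], [lo, 1.0 - lo]])
        out["v"][j] = A @ out["v"][j]
        out["eta"][j] = np.einsum("ab,bpr->apr", A, out["eta"][j])
        out["phi"][j] = np.einsum("ab,bpm->apm", A, out["phi"][j])
    return PosteriorDraws(
        draws=out, config=draws.config, seed=draws.seed,
        acceptance=dict(draws.acceptance), loglik_trace=draws.loglik_trace.copy(),
    )


def covariance_eigen(
    draws: PosteriorDraws,
    basis: BasisSystem,
    grid: np.ndarray,
    which: str | tuple[int, int] = "pooled",
) -> EigenSummary:
    """Eigen-decompose the reconstructed covariance surface per draw.

    ``which`` selects a feature pair (k, k') or ``"pooled"`` (average of the
    K within-feature covariances).  The discretized surface is symmetrized and
    decomposed with trapezoid quadrature weights so the eigenfunctions are
    orthonormal in L2 on the grid; eigenvalues are clipped at zero (they are
    nonnegative up to roundoff by construction).  Each eigenfunction's sign is
    fixed so its element of largest magnitude is positive.
    """
    grid = np.asarray(grid, dtype=float)
    G = grid.size
    S = eval_design(basis, grid)  # P x G
    w = np.empty(G)
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    sqw = np.sqrt(w)

    n_draws = draws.n_draws
    K = draws.config.K
    evals = np.zeros((n_draws, G))
    efuns = np.zeros((n_draws, G, G))
    for j in range(n_draws):
        phi = draws.draws["phi"][j]  # K x P x M
        if isinstance(which, tuple):
            k, k2 = which
            core = phi[k] @ phi[k2].T
        else:
            core = sum(phi[k] @ phi[k].T for k in range(K)) / K
        C = S.T @ core @ S
        C = (C + C.T) / 2
        Kw = sqw[:, None] * C * sqw[None, :]
        lam, vec = np.linalg.eigh(Kw)
        order = np.argsort(lam)[::-1]
        lam = np.clip(lam[order], 0.0, None)
        psi = vec[:, order] / sqw[:, None]
        # sign convention: largest-magnitude element positive
        for c in range(G):
            idx = np.argmax(np.abs(psi[:, c]))
            if psi[idx, c] < 0:
                psi[:, c] = -psi[:, c]
        evals[j] = lam
        efuns[j] = psi
    return EigenSummary(grid=grid, eigenvalues=evals, eigenfunctions=efuns,
                        which=str(which))


def summarize(
    draws: PosteriorDraws,
    basis: BasisSystem,
    x_values: list[np.ndarray] | None = None,
    grid: np.ndarray | None = None,
    quantiles: tuple[float, float] = (0.025, 0.975),
    z_trajectories: list[np.ndarray] | None = None,
    z_percentiles: tuple[float, ...] = (),
) -> dict[str, pd.DataFrame]:
    """Posterior summaries: feature-mean bands, allocation summaries, and
    trajectory estimates conditional on allocation values.

    Returns tidy tables: ``mean_bands`` (feature, x_label, t, median, lower,
    upper), ``allocations`` (curve, feature, median, lower, upper), and when
    requested ``trajectories`` for given allocation vectors z* (including ones
    derived from empirical percentiles of the posterior-median allocations).
    """
    for q in quantiles:
        if not 0 < q < 1:
            raise ValueError("quantiles must lie strictly inside (0, 1)")
    if grid is None:
        grid = np.linspace(basis.domain[0], basis.domain[1], 100)
    S = eval_design(basis, grid)  # P x G
    K, R = draws.config.K, draws.config.R
    if x_values is None:
        x_values = [np.zeros(R)]
    lo_q, hi_q = quantiles

    v = draws.draws["v"]  # (J, K, P)
    eta = draws.draws["eta"]  # (J, K, P, R)
    rows = []
    curves_by_x = {}
    for x in x_values:
        x = np.asarray(x, dtype=float).ravel()
        label = "x=" + ",".join(f"{xi:g}" for xi in x) if R else "x=()"
        coef = v.copy()
        if R:
            coef = coef + eta @ x
        curves = coef @ S  # (J, K, G)
        curves_by_x[label] = curves
        med = np.median(curves, axis=0)
        lo = np.quantile(curves, lo_q, axis=0)
        hi = np.quantile(curves, hi_q, axis=0)
        for k in range(K):
            for g, t in enumerate(grid):
                rows.append((k + 1, label, t, med[k, g], lo[k, g], hi[k, g]))
    mean_bands = pd.DataFrame(
        rows, columns=["feature", "x_label", "t", "median", "lower", "upper"]
    )

    Z = draws.draws["Z"]  # (J, N, K)
    z_med = np.median(Z, axis=0)
    z_lo = np.quantile(Z, lo_q, axis=0)
    z_hi = np.quantile(Z, hi_q, axis=0)
    alloc_rows = [
        (i, k + 1, z_med[i, k], z_lo[i, k], z_hi[i, k])
        for i in range(Z.shape[1])
        for k in range(K)
    ]
    allocations = pd.DataFrame(
        alloc_rows, columns=["curve", "feature", "median", "lower", "upper"]
    )

    tables = {"mean_bands": mean_bands, "allocations": allocations}

    zstars: list[tuple[str, np.ndarray]] = []
    if z_trajectories:
        zstars += [("z*=" + ",".join(f"{z:g}" for z in zs), np.asarray(zs, float))
                   for zs in z_trajectories]
    for pct in z_percentiles:
        # empirical percentile of the posterior-median allocation to feature 1
        q1 = float(np.quantile(z_med[:, 0], pct / 100.0))
        zp = np.zeros(K)
        zp[0] = q1
        if K == 2:
            zp[1] = 1.0 - q1
        else:  # distribute the remainder proportionally to the median profile
            rest = z_med[:, 1:].mean(axis=0)
            zp[1:] = (1.0 - q1) * rest / rest.sum()
        zstars.append((f"pct{pct:g}", zp))
    if zstars:
        traj_rows = []
        for x in x_values:
            x = np.asarray(x, dtype=float).ravel()
            label = "x=" + ",".join(f"{xi:g}" for xi in x) if R else "x=()"
            curves = curves_by_x[label]  # (J, K, G)
            for zlab, zs in zstars:
                mix = np.einsum("k,jkg->jg", zs, curves)
                med = np.median(mix, axis=0)
                lo = np.quantile(mix, lo_q, axis=0)
                hi = np.quantile(mix, hi_q, axis=0)
                for g, t in enumerate(grid):
                    traj_rows.append((zlab, label, t, med[g], lo[g], hi[g]))
        tables["trajectories"] = pd.DataFrame(
            traj_rows, columns=["z_label", "x_label", "t", "median", "lower", "upper"]
        )
    return tables
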