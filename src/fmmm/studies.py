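"""Reduced-scale runners for the two simulation studies.

These wrap the full pipeline (simulate, fit, post-process, score) so the
K-selection and structure-recovery studies can be reproduced end to end at a
configurable scale.  The study *conditions* (truth drawn once from the priors
under the frozen master seed, 25 observation points per curve, anchored
allocations, the K in {2,3,4,5} fit grid) are fixed by the synthetic module;
only chain lengths and replicate counts are chosen by the caller.
"""

from __future__ import annotations

import numpy as np

from .model_core import ModelConfig
from .postprocess import relabel_draws, rescale_to_separability
from .sampler import run_mcmc
from .selection_metrics import information_criteria, rmise, rmse_alloc
from .synthetic import draw_study_truth, simulate_dataset, study2_scenario

__all__ = ["run_k_selection_study", "run_recovery_study"]


def run_k_selection_study(
    n_replicates: int = 10,
    N: int = 60,
    n_points: int = 25,
    n_iter: int = 600,
    burn_in: int = 250,
    thin: int = 2,
    K_fits: tuple[int, ...] = (2, 3, 4, 5),
    n_restarts: int = 2,
    seed: int | None = None,
) -> dict:
    """Fit each simulated K=3, R=1 dataset with K in ``K_fits`` and count how
    often each criterion selects the true K.

    Each fit is restarted ``n_restarts`` times from different initializations
    and the restart with the highest maximum marginal likelihood is kept —
    the usual guard against the multimodality of mixed membership posteriors.
    Returns per-criterion selection counts and the criteria tables.
    """
    kwargs = {} if seed is None else {"seed": seed}
    sc = study2_scenario(n_datasets=n_replicates, N=N, n_points=n_points,
                         K_fits=K_fits, **kwargs)
    cfg3 = ModelConfig(K=3, P=sc["P"], M=sc["M"], R=1)
    truth, basis = draw_study_truth(cfg3, seed=sc["truth_seed"])
    counts = {"AIC": 0, "BIC": 0, "DIC": 0}
    tables = []
    for ds_seed in sc["dataset_seeds"]:
        data, _ = simulate_dataset(cfg3, N, n_points, seed=ds_seed,
                                   truth=truth, basis=basis)
        rows = {}
        for K in K_fits:
            best = None
            for r in range(n_restarts):
                cfg = ModelConfig(K=K, P=sc["P"], M=sc["M"], R=1,
                                  n_iter=n_iter, burn_in=burn_in, thin=thin)
                d = run_mcmc(data, cfg, seed=(ds_seed + 7919 * r) % 2**31,
                             basis=basis)
                fr = information_criteria(d, data, basis)
                if best is None or fr.max_loglik > best.max_loglik:
                    best = fr
            rows[K] = best
        aic_win = min(rows, key=lambda K: rows[K].aic)
        bic_win = max(rows, key=lambda K: rows[K].bic)
        dic_win = min(rows, key=lambda K: rows[K].dic)
        counts["AIC"] += aic_win == sc["K_true"]
        counts["BIC"] += bic_win == sc["K_true"]
        counts["DIC"] += dic_win == sc["K_true"]
        tables.append({K: (rows[K].max_loglik, rows[K].aic, rows[K].bic,
                           rows[K].dic) for K in K_fits})
    return {
        "n_replicates": n_replicates,
        "counts": counts,
        "rates_pct": {k: 100.0 * v / n_replicates for k, v in counts.items()},
        "tables": tables,
        "K_true": sc["K_true"],
    }


def _fit_and_score(data, truth, basis, cfg, fit_R, seed, rng, n_restarts=2):
    """Fit one model (possibly with the covariate dropped) and return
    feature-mean R-MISEs, marginal-mean R-MISEs, and allocation RMSE.

    The best of ``n_restarts`` chains by maximum marginal likelihood is kept.
    """
    from .functional_data import FunctionalDataset

    if fit_R == truth.R:
        fit_data = data
    elif fit_R == 0:
        fit_data = FunctionalDataset(
            data.curve_ids, data.times, data.values,
            np.empty((data.n_curves, 0)),
        )
    else:
        raise ValueError("only correct or covariate-dropped fits supported here")
    fit_cfg = ModelConfig(K=cfg.K, P=cfg.P, M=cfg.M, R=fit_R,
                          n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin)
    draws = None
    for r in range(n_restarts):
        cand = run_mcmc(fit_data, fit_cfg, seed=(seed + 104729 * r) % 2**31,
                        basis=basis)
        if draws is None or cand.loglik_trace.max() > draws.loglik_trace.max():
            draws = cand
    draws = relabel_draws(draws, basis)
    if fit_cfg.K == 2:
        draws = rescale_to_separability(draws)

    grid = np.linspace(basis.domain[0], basis.domain[1], 100)
    x_grid = np.linspace(-1.5, 1.5, 20)
    from .basis import eval_design

    S = eval_design(basis, grid)
    v_med = np.median(draws.draws["v"], axis=0)  # K x P
    # align fitted features to the truth by marginal mean curves
    true_marg = truth.v @ S
    est_marg = v_med @ S
    from itertools import permutations

    K = cfg.K
    perm = min(
        permutations(range(K)),
        key=lambda p: sum(np.sum((true_marg[k] - est_marg[p[k]]) ** 2)
                          for k in range(K)),
    )
    result = {"marginal_rmise": [], "mean_rmise": [], "alloc_rmse": None}
    for k in range(K):
        pk = perm[k]
        result["marginal_rmise"].append(rmise(
            lambda t, k=k: (truth.v[k] @ S),
            lambda t, pk=pk: (est_marg[pk]),
            grid,
        ))
        if fit_R == truth.R and truth.R > 0:
            eta_med = np.median(draws.draws["eta"], axis=0)
            result["mean_rmise"].append(rmise(
                lambda x, t, k=k: (truth.v[k] + truth.eta[k] @ np.atleast_1d(x)) @ S,
                lambda x, t, pk=pk: (v_med[pk] + eta_med[pk] @ np.atleast_1d(x)) @ S,
                grid, x_grid,
            ))
    Z_est = np.median(draws.draws["Z"], axis=0)
    result["alloc_rmse"] = rmse_alloc(truth.Z, Z_est[:, list(perm)])
    return result


def run_recovery_study(
    sample_sizes: tuple[int, ...] = (40, 80, 160),
    n_replicates: int = 3,
    n_points: int = 25,
    n_iter_base: int = 400,
    iters_per_curve: float = 5.0,
    thin: int = 2,
    n_restarts: int = 2,
    seed: int | None = None,
) -> dict:
    """Structure-recovery study for the K=2, R=1 scenario: correct fits and
    covariate-dropped (underspecified) fits across sample sizes.

    Chain length grows with the dataset (``n_iter_base + iters_per_curve*N``,
    burn-in 40%): larger datasets have sharper posteriors and need more sweeps
    to reach and explore the dominant mode.  Returns per-N medians over
    replicates of the covariate-adjusted mean R-MISE, the covariate-marginal
    mean R-MISE for both fits, and the allocation RMSE.
    """
    from .synthetic import MASTER_TRUTH_SEED

    truth_seed = MASTER_TRUTH_SEED if seed is None else seed
    truth_cfg = ModelConfig(K=2, P=8, M=2, R=1)
    truth, basis = draw_study_truth(truth_cfg, seed=truth_seed)
    rng = np.random.default_rng(truth_seed)
    out: dict = {"N": list(sample_sizes), "mean_rmise": [], "alloc_rmse": [],
                 "marginal_rmise_correct": [], "marginal_rmise_underspec": []}
    ss = np.random.SeedSequence(truth_seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31)
                 for s in ss.spawn(n_replicates * len(sample_sizes))]
    idx = 0
    for N in sample_sizes:
        n_iter = int(n_iter_base + iters_per_curve * N)
        cfg = ModelConfig(K=2, P=8, M=2, R=1, n_iter=n_iter,
                          burn_in=int(0.4 * n_iter), thin=thin)
        mr, ar, mc, mu = [], [], [], []
        for rep in range(n_replicates):
            ds_seed = rep_seeds[idx]
            idx += 1
            data, bundle = simulate_dataset(cfg, N, n_points, seed=ds_seed,
                                            truth=truth, basis=basis)
            correct = _fit_and_score(data, bundle.state, basis, cfg, 1,
                                     ds_seed % 2**31, rng,
                                     n_restarts=n_restarts)
            # a stuck underspecified fit only weakens the comparison against
            # it, so one chain suffices there
            underspec = _fit_and_score(data, bundle.state, basis, cfg, 0,
                                       (ds_seed + 13) % 2**31, rng,
                                       n_restarts=1)
            mr.append(np.mean(correct["mean_rmise"]))
            ar.append(correct["alloc_rmse"])
            mc.append(np.mean(correct["marginal_rmise"]))
            mu.append(np.mean(underspec["marginal_rmise"]))
        out["mean_rmise"].append(float(np.median(mr)))
        out["alloc_rmse"].append(float(np.median(ar)))
        out["marginal_rmise_correct"].append(float(np.median(mc)))
        out["marginal_rmise_underspec"].append(float(np.median(mu)))
    return out
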