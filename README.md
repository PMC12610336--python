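# fmmm — covariate-adjusted functional mixed membership models

`fmmm` fits Bayesian mixed membership models to functional data — curves such
as EEG power spectra, growth trajectories, or dose-response profiles — while
letting the latent functional features depend on scalar covariates.  Where a
clustering model forces every curve into exactly one group, a mixed membership
model gives each curve `i` a simplex-valued allocation vector
`z_i = (Z_i1, ..., Z_iK)` and models it as a convex combination of `K` latent
features.  The motivating use case is developmental neuroimaging: EEG alpha
spectra mix an aperiodic 1/f trend with a periodic alpha peak, both of which
change with age, so a model with age-dependent features and continuous
memberships is the natural description.

## Model

Feature `k` is a Gaussian process with covariate-linear mean expanded in a
`P`-dimensional equidistant-knot B-spline basis `B(t)`:

    mu_k(x, t) = (v_k + eta_k x)' B(t)

and the joint covariance of the `K` features is approximated by `M` scaled
pseudo-eigenfunctions `phi_km' B(t)` (a truncated multivariate Karhunen-Loeve
expansion).  Writing `S_i = B(t_i)` for the design at curve `i`'s observation
times, the sampling model conditional on scores `chi_im ~ N(0,1)` is

    Y_i(t_i) | Theta ~ N( sum_k Z_ik [ S_i'(v_k + eta_k x_i)
                          + sum_m chi_im S_i' phi_km ],  sigma^2 I ).

Priors: multiplicative gamma process shrinkage on the loadings, first-order
random-walk smoothing on the mean coefficients, a hierarchical Dirichlet prior
`z_i ~ Dir(alpha3 pi)` on the allocations, and an inverse-gamma noise prior.
Posterior simulation is Gibbs with Metropolis-Hastings on the constrained
blocks, optional Neal-style tempered transitions on the allocations, and
post-processing that resolves label switching and (for `K = 2`) enforces the
separability normalization that makes the model identifiable.  Model size `K`
is chosen by AIC/BIC/DIC, a log-likelihood elbow table, and pseudo-marginal
likelihoods built from conditional predictive ordinates.  See
`docs/methods.md` for the full specification.

## Worked example

```python
from fmmm import ModelConfig, simulate_dataset, run_mcmc
from fmmm import relabel_draws, rescale_to_separability
from fmmm import information_criteria, rmse_alloc
from fmmm.synthetic import draw_study_truth

cfg = ModelConfig(K=2, P=8, M=2, R=1, n_iter=600, burn_in=250)
truth_state, basis = draw_study_truth(cfg)  # frozen two-feature study truth
data, truth = simulate_dataset(cfg, n_curves=60, n_points=25, seed=7,
                               truth=truth_state, basis=basis)

# mixed membership posteriors are multimodal: keep the best of two restarts
candidates = [run_mcmc(data, cfg, seed=s, basis=basis) for s in (7, 8)]
draws = max(candidates, key=lambda d: d.loglik_trace.max())
draws = rescale_to_separability(relabel_draws(draws, basis))

fit = information_criteria(draws, data, basis)
print(f"max log-likelihood {fit.max_loglik:.1f}")
print(f"AIC {fit.aic:.1f}  BIC {fit.bic:.1f}  DIC {fit.dic:.1f}")
print(f"allocation RMSE vs truth {rmse_alloc(truth.state.Z, draws):.3f}")
```

which prints:

```
max log-likelihood -11.6
AIC 153.2  BIC -289.4  DIC 118.3
allocation RMSE vs truth 0.066
```

The allocation RMSE of 0.066 means each curve's estimated membership weights
sit within about seven percentage points of the generating ones; the criteria
row is what `select-k` compares across candidate `K` (AIC/DIC smallest best,
BIC largest best).

The same pipeline is available from the shell:

```sh
fmmm simulate --config cfg.yaml --seed 7 --out sim/
fmmm fit      --config cfg.yaml --seed 7 --out fit/
fmmm select-k --config cfg.yaml --k-values 2,3,4 --out selk/
fmmm report   --config cfg.yaml --draws fit/draws.h5 --out report/
```

with a YAML config holding the model dimensions, priors, MCMC settings and
data paths (`fmmm simulate` writes `curves.csv` / `covariates.csv` that
`fmmm fit` reads back; every output directory contains the exact config and
seed used).

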