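# Methods

## Model

Each observed curve `Y_i`, sampled at `n_i` time points `t_i` in a compact
interval, is modeled as a convex combination of `K` latent functional features.
Membership is encoded by allocation vectors `z_i` on the unit simplex
(`Z_ik >= 0`, `sum_k Z_ik = 1`): an observation may belong fractionally to
several features, generalizing hard clustering.  Feature `k` is a Gaussian
process whose mean depends linearly on an `R`-vector of standardized scalar
covariates `x_i`,

    mu_k(x, t) = (v_k + eta_k x)' B(t),

where `B(t)` is a `P`-dimensional B-spline basis with equidistant interior
knots, `v_k` the population-level coefficients and `eta_k` (`P x R`) the
covariate effects.  The joint covariance across the `K` features is
approximated by a truncated multivariate Karhunen-Loeve expansion with `M`
*pseudo-eigenfunctions* `phi_km' B(t)`: the `phi` directions are not
constrained to be orthogonal (so the sampler works on an unconstrained space);
the true eigen-structure is recovered afterwards by eigendecomposing the
reconstructed covariance surface.  Conditional on standard-normal factor
scores `chi_im`,

    Y_i(t_i) | Theta ~ N( sum_k Z_ik [ S_i'(v_k + eta_k x_i)
                           + sum_m chi_im S_i' phi_km ],  sigma^2 I ),

with `S_i = B(t_i)` the `P x n_i` design.  Integrating the scores out gives a
dense Gaussian likelihood whose covariance is `V(t_i, z_i) + sigma^2 I` with
`V = S_i' Theta_i Theta_i' S_i`, `Theta_i = sum_k Z_ik phi_k`; all marginal
computations use this rank-`M` structure through the matrix
inversion/determinant lemma with a Cholesky factorization of the `M x M`
capacitance matrix (fixed jitter `1e-10 * trace/M` retried once on failure).

### Priors

* **Loadings:** multiplicative gamma process (MGP) shrinkage.
  `phi_kpm ~ N(0, gamma_kpm^-1 tau~_mk^-1)`, `gamma_kpm ~ Ga(nu/2, nu/2)`,
  `tau~_mk = prod_{n<=m} delta_nk`, `delta_1k ~ Ga(a1_k, 1)`,
  `delta_jk ~ Ga(a2_k, 1)` for `j >= 2`, `a1_k ~ Ga(alpha_1, beta_1)`,
  `a2_k ~ Ga(alpha_2, beta_2)` with `alpha_2 > beta_2` so the cumulative
  precisions grow stochastically with `m` and higher-index loadings shrink
  toward zero.
* **Mean coefficients:** first-order random-walk (RW1) smoothing,
  `p(v_k | tau_vk) ∝ exp(-tau_vk/2 * sum_p (v_pk - v_(p+1)k)^2)`, applied
  likewise to each covariate column of `eta_k`; `tau ~ Ga(alpha, beta)`.  The
  prior is improper (flat in the constant direction); an optional proper
  Gaussian ridge anchor `N(0, ridge^-1 I)` is available (`ModelConfig.ridge`),
  in which case the coefficient prior is the properly normalized
  `N(0, (tau D'D + ridge I)^-1)`.
* **Allocations:** hierarchical Dirichlet, `z_i ~ Dir(alpha3 * pi)`,
  `pi ~ Dir(c_pi 1)`, `alpha3 ~ Exp(b)`.
* **Noise:** `sigma^2 ~ IG(alpha_0, beta_0)`.

Defaults (`Hyperparameters`): `nu=3, alpha_1=2, beta_1=1, alpha_2=3, beta_2=1,
alpha_v=beta_v=alpha_eta=beta_eta=1, c_pi=10, b=1, alpha_0=beta_0=1`.  These
are configuration values, not claims about any particular dataset; every one
is overridable from the YAML config.

## Posterior computation

One sweep updates, in a fixed order for reproducibility: factor scores
(Gaussian conditional per curve), loadings (Gaussian conditional per `(k, m)`
block), mean coefficients (`v_k` jointly over `p`; `eta` per covariate
column), noise variance (conjugate inverse gamma), MGP block (conjugate gamma
for `gamma` and sequential `delta`; log-scale random-walk MH for `a1, a2`),
RW1 smoothing precisions (conjugate gamma when `ridge = 0`; with a ridge
anchor the gamma draw becomes the proposal of an exact independence MH step,
because the proper normalizer `|tau D'D + ridge I|^{1/2}` differs from the
improper `tau^{(P-1)/2}`), allocations, and the Dirichlet hyper-layer
(`pi` by additive-log-ratio random walk, `alpha3` by log-scale random walk).

**Allocations.** Each `z_i` is updated by MH with a Dirichlet random-walk
proposal `z' ~ Dir(kappa z_i + 0.05)` targeting the *score-marginalized*
likelihood times the `Dir(alpha3 pi)` prior.  Marginalizing `chi` removes the
tight `z`–`chi` coupling and mixes far better; the pair (marginal `z` step,
then a fresh draw of `chi | z`) is a valid partially collapsed Gibbs step, and
the sweep order guarantees `chi` is refreshed before anything conditions on it
again.  `kappa` and the MH step sizes adapt during burn-in toward 20–40%
acceptance and are frozen afterwards.

**Tempered transitions.** Optionally (every `temper_interval` sweeps) the
allocation block moves through a geometric ladder of `L` inverse temperatures
from 1 to `beta_min` (default 0.1) applied to the likelihood only, with one MH
sweep per rung up and down and a single global accept/reject; an empty ladder
is exactly one plain sweep.  Tempering targets the multimodality of
membership/label configurations; conjugate blocks stay plain Gibbs.

**Initialization.** Per-curve ridge basis fits are clustered with k-means;
allocations start at 0.8 on the assigned cluster and 0.2 spread uniformly;
`v` from allocation-weighted least squares; `eta`, `phi`, `chi` small random;
`sigma^2` from the initial residuals.  Multimodality is the dominant failure
mode, so the study runners also take the best of `n_restarts` chains by
maximum marginal likelihood.

### Sampler validation

Correctness of every update is established by a Geweke "getting it right"
joint-distribution test (`fmmm.sampler.geweke_test`): the
marginal-conditional simulator (ancestral draws of parameters then data) and
the successive-conditional simulator (full sweep alternated with data
re-simulation, plus a random label-permutation move that is valid by model
symmetry) must generate the same joint distribution.  First and second
moments of `v`, `sigma^2` and `Z` are compared with autocorrelation-robust
(Geyer initial-positive-sequence) standard errors.  The test model uses a
unit-scale ridge anchor (the improper RW1 prior cannot be sampled
ancestrally) and an `IG(5, 4)` noise prior so that the compared `sigma^2`
moments exist.  Statistics of the MGP layer itself are reported as a bounded
transform (`phi^2/(1+phi^2)`) only: under the MGP prior, `delta` shapes can be
arbitrarily small, giving `log delta` and any unbounded transform of `phi`
power-law tails with infinite variance; their sample means are not comparable
at any feasible chain length (the individual gamma/delta/a conditionals are
instead verified exactly against closed forms and by a data-free prior-cycle
test).  The allocation MH kernel is additionally checked against a brute-force
201-cell grid posterior on a two-curve toy (total variation < 0.02).

## Post-processing

* **Relabeling:** per draw, the feature permutation minimizing the summed L2
  distance between its mean curves at `x = 0` and those of the maximum
  marginal-likelihood draw (deterministic, truth-free reference), applied
  simultaneously to `v`, `eta`, `phi`, the MGP blocks, `Z` columns and `pi`.
* **Separability rescaling (K = 2):** per draw, `Z'_i1 = (Z_i1 - m)/(M+ - m)`
  with `m, M+` the observed min/max, so each feature gains a pure anchor
  observation; the feature blocks get the compensating linear mix
  `f' = A f`, `A = [[M+, 1-M+], [m, 1-m]]`, which preserves
  `sum_k Z_ik f(k)` exactly — and hence every draw's likelihood, mean and
  covariance structure.  Draws with all allocations equal are left unchanged.
  For three or more features the analogous normalization needs the
  sufficiently-scattered machinery and is out of scope; relabeling still
  applies at any `K`.
* **Eigen-analysis:** the covariance surface reconstructed from each draw is
  discretized on a grid, symmetrized, and eigendecomposed with trapezoid
  quadrature weights so eigenfunctions are orthonormal in L2(grid); signs are
  fixed so each eigenfunction's largest-magnitude element is positive.
* **Summaries:** pointwise posterior medians and central credible bands
  (default 95%) for feature means at requested covariate values, allocation
  summaries, and trajectory estimates at fixed allocation vectors `z*`
  (including ones derived from empirical percentiles of the posterior-median
  allocations).  Pointwise rather than simultaneous bands.

## Model selection and metrics

With `Lhat` the maximum over stored draws of the marginal likelihood and
`p = K P (1+R) + K P M + 1` the count of structural parameters:

* `AIC = 2p - 2 log Lhat` (smallest best),
* `BIC = 2 log Lhat - p log(N)` on the largest-is-best sign convention
  (the conventional negative is also reported), with `N` the number of
  curves,
* `DIC = 2 Dbar - D(theta~)` with deviance `D = -2 log L`, `Dbar` the
  posterior mean and `theta~` the maximum-likelihood draw (a plug-in that
  always satisfies the simplex constraints, unlike a posterior mean of
  allocations),
* per-curve conditional predictive ordinates
  `CPO_i = (S^-1 sum_s p(Y_i | theta_s)^-1)^-1` computed in log space, and the
  pseudo-marginal likelihood `PsML = sum_i log CPO_i`,
* `R-MISE = 100% * int (f - fhat)^2 / int f^2` by trapezoid quadrature (over
  `t`, and additionally over a covariate grid for covariate-adjusted
  surfaces), and allocation RMSE after the feature permutation minimizing it.

The parameter-count and sample-size conventions are pinned once and used
across all `K` so comparisons are consistent.  Latent per-curve quantities
(allocations, factor scores) are not counted as parameters, following the
standard finite-mixture convention; counting the `N(K-1)` allocation
coordinates would make the BIC penalty difference between successive `K`
grow linearly in `N` — strictly faster than the log-likelihood evidence
itself — so BIC could never detect an additional feature at any sample size.
`N` (curves) rather than `n_tot` (points) enters the BIC penalty because
curves are the independent replication units: points within a curve are
correlated under the marginal model, and information about the structural
parameters accrues with `N` at a fixed observation grid.

## Synthetic data generator

`simulate_dataset` draws from the model's own sampling structure: covariates
standard normal then standardized; `z_i ~ Dir(1.5 * 1)`; `chi_im ~ N(0,1)`;
observations on a regular grid (default domain [0, 1]) with `N(0, sigma^2)`
noise, `sigma^2 = 0.05` by default.  One pure observation is planted per
feature so the separability condition holds by construction in study data.

Study truths are drawn once from the prior stack under the frozen master seed
`20240612` and then normalized into a recoverable regime:

1. feature mean curves are redrawn (per feature) until every pairwise L2
   distance is at least 1.0 — an unseparated truth is unidentifiable in
   practice;
2. each feature's loadings are rescaled so the square root of its covariance
   trace equals 0.3 times the smallest separation.  The MGP prior alone puts
   no scale hierarchy on a single draw, and unnormalized draws routinely gave
   within-feature process variation *larger* than the between-feature mean
   differences — a regime in which neither allocations nor means are
   recoverable at any realistic sample size.  The 0.3 ratio encodes the
   qualitative hierarchy of the motivating EEG features (distinct mean shapes,
   moderate subject-level variation, small measurement noise).

What the generator does *not* emulate: the spectral shape of real EEG curves
(1/f trends, alpha peaks), irregular or subject-specific observation grids,
non-Gaussian noise, and covariate distributions other than standardized
Gaussians.  Passing recovery tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
model misspecification.

## Study problem sizes

The two simulation studies are run at reduced scale by default (the full
designs are cluster-scale):

* **K-selection study:** datasets from the frozen `K=3, R=1` truth with
  `N = 120`, `n_i = 25`, `P = 8`, `M = 3`; fits `K in {2, 3, 4, 5}`, chains of
  500 sweeps (200 burn-in, thinning 2), best of 2 restarts; 3 replicates in
  the test suite and acceptance script.  Expected behavior: BIC selects
  `K = 3` most reliably; AIC and DIC tend toward more complex models; the
  log-likelihood elbow sits at `K = 3`.
* **Recovery study:** the frozen `K=2, R=1` truth, `N in {40, 80, 160}`,
  `n_i = 25`, 3 replicates per `N`, best of 2 restarts per correct fit;
  chain length grows with the dataset (`400 + 5N` sweeps, 40% burn-in),
  since larger datasets have sharper posteriors and need more sweeps to
  reach the dominant mode.  Correct fits are compared against
  covariate-dropped (underspecified) fits.  Expected behavior: median R-MISE
  of the covariate-adjusted means and median allocation RMSE decrease with
  `N`; underspecified fits have uniformly higher marginal-mean R-MISE.  Note
  that per-curve allocation error has an `n_i`-limited floor, so the
  allocation-RMSE decrease flattens once feature-mean uncertainty stops
  dominating (around `N ~ 100` under the default generator conditions).

## Numerical choices and limitations

* Rank decisions use singular values above `1e-8` times the largest.
* Standardization uses the sample (n-1) standard deviation; effects map back
  to raw units via the recorded centers/scales.
* Duplicate `(id, t)` rows are an error, never averaged.
* The Dirichlet proposal adds a floor of 0.05 to all concentrations so
  proposals stay proper near simplex vertices.
* Right-endpoint basis evaluation uses the left-limit convention.
* Heavy-tailed MGP scales mix slowly; for small datasets the effective sample
  size of `tau~`-related functionals is far below the nominal draw count.
* `K >= 3` separability-style normalization and covariate-dependent
  covariance structures are out of scope.
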