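# Methods

This note documents the statistical model, the synthetic-data generator,
the sampler, and the numerical and design choices behind `aedesmap`.

## Model

Trap counts are modelled as conditionally independent draws from a count
family with log-linear mean,

    y_i ~ family(mu_i, ...),    log mu_i = beta0 + x_i' beta + u(s_i),

with three families sharing the same linear predictor:

| family  | parameters | mean / variance |
|---------|------------|-----------------|
| Poisson | —          | mu / mu |
| Negative binomial | size n > 0 | mu / mu + mu²/n |
| Zero-inflated Poisson | pi0 in [0,1) | (1−pi0)·mu / (1−pi0)·mu·(1+pi0·mu) |

The NB is parameterised by mean and size so that n → ∞ recovers the
Poisson; the ZIP places extra mass pi0 at zero on top of the Poisson
component.  All covariates are centered and scaled on the fitting data
(sample sd, ddof = 1), so a coefficient is a log incidence rate ratio per
1-SD increase and zero is the covariate mean.  Weather enters as the
single daily value on the observation date (lag 0) or 7/14 days earlier
(lag 1/2) — deliberately not weekly means, to preserve the daily
resolution of the driver.  Interaction columns are products of the
standardized parents and are not re-standardized; their coefficients read
as the change in one variable's effect per 1-SD of the other.

### Spatial random effect

`u` is a site-level, time-constant Gaussian field with Matérn covariance
of smoothness nu = 1 (the conventional 2-D default of the SPDE
representation, alpha = 2 ⇒ nu = alpha − d/2 = 1):

    C(d) = sigma² (kappa d) K1(kappa d),  kappa = sqrt(8)/rho.

`rho` is the *range* in the correlation-≈0.1 convention: the Matérn(1)
correlation at d = rho is sqrt(8)·K1(sqrt(8)) ≈ 0.139.  Coordinates are
projected planar kilometres with Euclidean distances — at a ~10-km urban
extent, curvature is negligible.  A jitter of 1e-8·sigma² on the diagonal
stabilises Cholesky factorizations.

### Priors

* Range and field sd get penalized-complexity priors, calibrated in closed
  form from two interpretable tail statements:
  P(rho < rho0) = p_rho gives pi(rho) = (lam/rho²)·exp(−lam/rho) with
  lam = −rho0·ln p_rho; P(sigma > sigma0) = p_sigma gives
  pi(sigma) = lam·exp(−lam·sigma) with lam = −ln(p_sigma)/sigma0.
  Defaults rho0 = 10 km, p_rho = 0.95 (observations farther apart than
  half the study width are unlikely to be correlated) and sigma0 = 0.5,
  p_sigma = 0.05 (the field is expected to be small relative to the
  covariate effects).  The CDF statements hold exactly; the test suite
  also verifies them by numerical integration.
* Fixed effects: Normal(0, 10²) on the standardized scale — effectively
  flat at the n ≈ 5,000 information level, proper enough to regularise
  degenerate designs.
* NB size: exponential prior on 1/sqrt(n) (a PC-style penalty on the
  departure from the Poisson base model), with rate ln 20 ≈ 3.0 so that
  P(n < 1) = 0.05.
* ZIP zero-inflation: flat Beta(1, 1).

## Inference

Sampling is exact MCMC on the joint posterior; no nested-Laplace or mesh
approximation is used because ~50 sites make the dense-GP linear algebra
trivial (51×51 Cholesky per hyperparameter proposal).  One iteration
combines:

1. **Coefficients** — component-wise Gaussian random-walk Metropolis with
   per-coordinate scales adapted during warmup toward 0.44 acceptance
   (diminishing adaptation, frozen afterwards).
2. **Field** — elliptical slice sampling on the *whitened* field
   z = (sigma·L)⁻¹ u (two sweeps per iteration).  ESS is tuning-free and
   its whitened form decouples z from (rho, sigma).
3. **Hyperparameters** — interweaved updates in log space: a non-centred
   random-walk move (z fixed, u recomputed) and a centred move (u fixed,
   only the field prior density changes, z recomputed).  Alternating the
   two parameterisations mixes (rho, sigma) whether the field is
   data-dominated or prior-dominated; either alone stalls in one regime.
4. **Coefficient/field shear moves** — for each coefficient j, propose
   beta_j → beta_j + delta with the field compensated through the
   within-site covariate mean, u → u − delta·x̄_j.  For site-constant
   covariates (land cover, SES, intercept) the likelihood is exactly
   invariant, so this slides along the beta/field ridge that blocks
   centred alternation.  Unit-Jacobian shear; standard Metropolis accept.
5. **Family parameters** — random walks on log n and logit pi0.

Chains are initialised from a ridge-penalised Poisson mode (hand-coded
L-BFGS on the exact posterior; the same optimiser exposes
`map_estimate()`, which for the non-spatial Poisson model agrees with an
independent IRLS fit to ~4 decimals and is used as an oracle check).
Per-chain seeds derive deterministically from one master seed.

Convergence: split rank-normalized R-hat and Geyer bulk ESS per scalar
parameter; `fit()` raises by default when any R-hat exceeds 1.05
(`rhat_action="warn"` downgrades to a logged warning for scripted batch
runs, with the full table still attached to the results).

### DIC and overdispersion

DIC = D̄ + pD with pD = D̄ − D(θ̄), using the *conditional* deviance given
the latent field; the plug-in θ̄ is the posterior mean of the linear
predictor and of the family parameters.  The same definition applies to
spatial and non-spatial fits, so the family-comparison ordering is
coherent.  The Pearson overdispersion statistic is computed per posterior
draw, Σ(y−m)²/V(m) / (N−p), with m and V the family marginal mean and
variance and p the number of fixed effects (hyperparameters are not
counted — the statistic is a fixed-effect residual diagnostic); the
reported point and 95% interval are the posterior mean and 2.5/97.5
percentiles across draws.

## Variable selection

Candidates get an NMIG spike-and-slab prior: beta_j | gamma_j ~
N(0, gamma_j v1 + (1−gamma_j) v0), gamma_j ~ Bernoulli(w), with
v0 = 0.005², v1 = 2.5², w = 0.5 — weakly informative on standardized
covariates.  The sampler collapses gamma (beta moves under the mixture
prior, with occasional independence proposals drawn from the prior itself
so spike↔slab jumps never depend on the adapted step size) and draws
gamma_j | beta_j from its exact Bernoulli conditional; reported inclusion
probabilities are Rao-Blackwellized.  The likelihood during selection is
negative binomial with the same size prior as the main model — the terms
enter linearly (no smooth bases), since the final models are linear in the
chosen predictors.  Correctness is checked against brute-force enumeration
of all gamma configurations under a conjugate Gaussian working likelihood
on a tiny instance, and against the no-information limit (inclusion → w).

Choice rule: within each weather variable only the lag with the largest
|posterior-mean effect| stays in contention; candidates are then
shortlisted to the top 12 by inclusion probability and the six with the
largest |scaled effect| are selected, with alphabetical tie-breaks at the
boundary (logged).  Scaled effects are posterior means of beta_j ranked by
absolute value; posterior medians would be an equally defensible reading
of "estimated scaled effect size".

## Synthetic-data generator

The generator emulates a one-year urban surveillance campaign:

* **Layout** — n_sites (default 51) uniform in a square extent (default
  10 km); per-site observation counts Poisson(100) truncated at 30
  (mirroring a ≥30-observation retention rule), giving ~5,000 rows with
  unbalanced schedules; observation dates are random thinnings of the
  year.
* **Weather** — daily seasonal sinusoids plus AR(1) noise; humidity is
  driven by a mixture of the temperature process and an independent
  process so the default association lands near Spearman rho ≈ 0.6.
  Weather is shared across sites (1-km-grid covariates at a ~10-km extent
  are nearly common anyway).
* **Covariates** — site-level variables are standard normal (after
  standardization only the standardized distribution matters);
  `impervious` and `grass`, when both requested, are drawn with
  correlation −0.67 because paving and lawn are zero-sum land covers.
* **Field and counts** — one Matérn(nu=1) field draw per dataset
  (site-level, constant over the year), then counts from the chosen
  family.

Two scenarios freeze the study conditions, using published fitted
coefficients as generating truths: an abundant species (intercept 1.59,
NB size 1.5, range 0.9 km — ≈15–18% zeros, counts to ~200) and a rare one
(intercept −1.50, NB size 0.8, range 1.0 km — ≈80% zeros).  The field sd
is 0.3 in both: it is not printed in the source analysis and was chosen
once as plausible under the prior statement P(sigma > 0.5) = 0.05.  What
the generator does **not** emulate: real geography and land-cover maps,
non-random trap placement, observation-time-of-day effects, temporally
varying spatial structure, and the exact marginal zero fractions
(17.7%/84.0%) of the real data — those depend on unpublished covariate
distributions, so the scenarios match them only qualitatively.  Passing
recovery tests therefore demonstrate correctness of the machinery under
the model's own assumptions, not fidelity to Brownsville.

## Validation and prediction

Posterior-predictive checks draw one parameter set per replicate (1,000 by
default), simulate a full dataset from each, and compare the observed
count histogram to pointwise 2.5–97.5 percentile bands per count value
(bins 0..max(observed, 99th simulated percentile)); a simultaneous band
would be wider and is not used.  Scaled residuals are Pearson residuals at
the posterior-mean fit — consistent with the overdispersion statistic —
with observed quantiles compared to the simulated envelope.

Grid prediction kriges the field per posterior draw (conditional Gaussian
given the site values under that draw's Matérn parameters) and mixes means
and variances across draws, so hyperparameter uncertainty propagates; far
from all sites the field mean reverts to 0 and the sd to the posterior
mean of sigma.  Weekly covariates apply lags to the daily series first,
then average within ISO weeks, then transform with the frozen training
standardization constants.  Predicted counts are sampled from the fitted
family per draw/cell/week — one trap-night per cell-week, no offset — and
summarised as means with 2.5/97.5 percentile bounds; the citywide weekly
series is exposed as both the sum and the mean over cells.  Weekly-series
interval bounds are sums of per-cell pointwise bounds, a conservative
band rather than a joint predictive interval.

## Problem sizes and reproducibility

Default study conditions are 51 sites / ~5,000 observations.  The test
suite runs its recovery studies at these sizes with 2 chains of 1,000
draws after 1,000 warmup (and smaller fixtures for structural tests); the
acceptance script uses 1,200/1,200 and averages each recovered quantity
over three replicate simulated datasets (median of posterior medians for
the range), which damps the realization noise of a single 51-site field
draw without changing the estimand.  All randomness flows from explicit
seeds; identical configurations reproduce byte-identical artifacts.

## Known limitations

* The spatial range is weakly identified from ~50 sites when the true
  range is below the typical nearest-neighbour spacing; its posterior
  leans on the PC prior (prior median ≈ 0.74 km at the default
  calibration) and its posterior median scatters substantially across
  data realizations.
* The field is static in time; seasonal hot-spot migration would require
  a space-time interaction the model deliberately omits.
* ZIP fits report zero inflation of the *count* distribution only; no
  covariates enter the zero-inflation component.
* DIC is the only fit criterion (matching the analysis design); no WAIC
  or cross-validation is provided.
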