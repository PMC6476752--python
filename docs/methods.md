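# Methods

## The model

`gensmr` estimates the abundance N and density D = N / |S| of an animal
population on a rectangular state space S from three data streams:

1. **Marking** (live traps, occasions k = 1..K_mark). Each individual i
   carries a latent activity center s_i ~ Uniform(S). The per-occasion
   capture probability at trap j is

       p_ij = lam0_mark * exp(-d_ij^2 / (2 sigma^2)),

   a half-normal decay in the distance d_ij between center and trap.
   Capture histories w_ijk are Bernoulli(p_ij) on effort-on trap-occasions.
   Individuals captured at least once are the m *marked* animals. A
   complementary-log-log variant, p_ij = 1 - exp(-lam0_mark * k(d_ij)),
   is available through `ModelConfig.marking_model = "cloglog"` for users
   who prefer a hazard-scale baseline.

2. **Resighting** (cameras, occasions k = 1..K_res). Complete encounter
   counts are Poisson with rate

       lambda_ij = lam0_resight * exp(-d_ij^2 / (2 sigma^2)).

   A marked animal that is photographed is individually *identified* with
   probability delta. By Poisson thinning, the identified counts y^m_ijk
   are Poisson(delta * lambda_ij) and the detections of marked-but-
   unidentified animals enter only through their per-camera-occasion sums

       nnid_jk ~ Poisson((1 - delta) * sum_{i <= m, alive_ik} lambda_ij).

   Counts of unmarked animals are Poisson with mean
   sum over the (latent) unmarked part of the population of lambda_ij.
   Because the mean is occasion-constant given effort, the sampler works
   with occasion-aggregated unmarked counts (an equivalent likelihood up to
   a data-only multinomial constant).

3. **Telemetry.** GPS fixes of marked animals are bivariate normal around
   s_i with standard deviation sigma on each axis. Telemetry is what keeps
   sigma (and through it lam0_resight) identifiable even when no marked
   animal is ever identified on camera (delta = 0).

A binary `alive[i, k]` matrix removes a marked individual from both marked
resighting means after a known death; a binary detector-occasion effort
matrix multiplies all means.

**Unknown N** is handled by data augmentation: a fixed superpopulation of
size M with inclusion indicators z_i ~ Bernoulli(psi) and psi ~ Uniform(0,1),
which induces a discrete-uniform prior on N over 0..M. The first m slots
are the marked animals (z = 1 observed); augmented slots with z_i = 1 are
real-but-unmarked animals and therefore contribute an all-zero marking
history — this is what lets the marked sample be spatially non-random
without biasing N (the "generalized" part of generalized mark-resight).

Priors: lam0_mark ~ U(0,1), lam0_resight ~ U(0,2), psi ~ U(0,1),
delta ~ U(0,1), sigma ~ U(0, sigma_max) with sigma_max defaulting to half
the longer side of S (any scale the detector array can inform lies well
inside), s_i ~ Uniform(S). The z ~ Bernoulli(psi) terms cover all M slots,
marked included, so psi's Beta full conditional uses N = sum z directly.

## Sampling

`run_mcmc` is a Metropolis-within-Gibbs sampler with the unidentified
histories marginalized analytically. Per sweep:

* activity centers: Gaussian random-walk Metropolis per individual
  (proposals outside S are rejected — the uniform prior's support);
  centers of z = 0 slots are refreshed from Uniform(S), their exact
  conditional;
* z_i (augmented slots): exact Gibbs with odds psi/(1-psi) times the
  all-zero marking-history probability times the likelihood ratio of the
  unmarked counts with/without the slot's kernel column (computed via
  rank-1 updates of the per-camera totals);
* psi: Beta(1 + sum z, 1 + M - sum z);
* delta: Beta(1 + total identified events, 1 + total unidentified-marked
  events). The conditional is free of every other parameter because the
  delta-dependence of the thinned Poisson means cancels between the
  identified and unidentified streams;
* lam0_mark (logit scale), lam0_resight and sigma (log scale): random-walk
  Metropolis with the appropriate Jacobians, hard rejection outside the
  prior support.

Proposal scales adapt in windows of 50 sweeps toward 30-45% acceptance
during a warm-up phase only (`n_adapt`, default 1,000 sweeps), preserving
detailed balance afterwards; the default run is 5,000 post-adaptation
sweeps with 1,000 discarded as burn-in. The kernels are numba-compiled;
distance and kernel matrices are cached and updated by rows, with the
running camera totals rebuilt every sweep to prevent floating-point drift.
The sampler aborts with a diagnostic on a non-finite joint density and
warns when more than 1% of posterior mass sits at N = M (M too small).

`run_mcmc_latent` is an independently coded cross-check that imputes the
per-individual unidentified histories instead of marginalizing them. Given
the cell sums nnid_jk, the vector of individual contributions is exactly
Multinomial(nnid_jk, p_i proportional to alive_ik * lambda_ij) — the full
conditional implied by Poisson thinning — so the imputation is a Gibbs
draw, redrawn every sweep, and the conditional (unmarginalized) Poisson
likelihood replaces the marginal one everywhere. Agreement of the two
samplers' posteriors is part of the test suite. When nnid is identically
zero the two samplers consume identical random streams and produce
identical chains, which the suite also checks.

## Synthetic data

The simulator reproduces the reference study design: N = 50 centers on the
state space, sigma = 0.05 units, a 5x5 live-trap grid at 0.15 spacing run
for 5 occasions, a 10x10 camera grid at 0.066 spacing run for 4 occasions
with lam0_resight = 0.5, marked-count levels m in {5, 10, 15, 20} paired
element-wise with lam0_mark in {0.05, 0.15, 0.25, 0.35}, ten equally
spaced delta values, and 50 replicates per (m, delta) cell. Within one
replicate all delta values share the same population and full resighting
histories; only the binomial identification thinning is redrawn, so the
delta comparison is paired. Telemetry is 100 fixes per marked animal
(unstated in the design; 100 pins sigma to about 1% without dominating
runtime — it is the knob that controls how much the telemetry informs
sigma). All streams derive from one master seed via `SeedSequence`, so any
replicate is reproducible in isolation.

Two design points deserve emphasis because they were genuinely open:

* **State space.** The design's detector envelope expanded by
  2.5 * sigma on each side (a 0.85 x 0.85 square, area 0.7225). On this
  space the simulation study reproduces the reference bias/RMSE/coverage
  table. A much larger space (e.g. the unit square) leaves a third of S
  without camera coverage; abundance there is extrapolated through psi,
  which inflates both the spread of the estimator and the pull of the
  uniform prior on N.
* **Marked count per cell.** The marked count is the random outcome of
  the marking process; `m_target` labels the cell. Conditioning the
  populations on an exact marked count (rejection resampling) selects
  center configurations the fitted model does not condition on — e.g.
  forcing m = 20 where the design's expectation is 29 yields populations
  depleted near the detectors and a clearly negatively biased estimator.
  `ScenarioSpec(exact_m=True)` (the default for standalone datasets)
  still enforces an exact count when a fixture needs one; the study suite
  sets `exact_m=False`.

What the generator does **not** emulate about field data: temporally
autocorrelated GPS fixes, home ranges that deviate from a stationary
isotropic bivariate normal, unmodeled heterogeneity in detection,
mis-assignment of the marked/unmarked status (records of unknown status
are assumed discarded), and non-rectangular habitat. Passing tests
therefore demonstrate correctness of the estimator under the model's own
assumptions, not robustness to their violation.

## Numerical choices

* Empirical HPD intervals by the shortest sorted window containing
  ceil(level * n) draws (Chen-Shao); for unimodal posteriors this
  converges to the true HPD region.
* Posterior mode of N by integer tabulation (ties to the smallest value);
  continuous parameters by the tallest Freedman-Diaconis histogram bin.
* Gelman-Rubin R-hat in the classic non-split form by default (matching
  the convention of the era the model comes from); `split=True` available.
* Monte-Carlo standard errors by batch means (30 batches), robust to
  chain autocorrelation.
* A simulation-study replicate is marked failed when its chain hits a
  non-finite density or (multi-chain runs) R-hat on N exceeds 1.5; failed
  replicates are counted and excluded from cell aggregates, never silently
  dropped.
* Initialization: marked centers at the centroid of each animal's fixes
  and detections; sigma at the pooled telemetry standard deviation
  (override via `sigma_init`; an error if neither exists, since sigma
  would be unidentifiable); delta at the posterior mean of its conjugate
  update; rates at prior midpoints; augmented z at fair coin flips.

## Fitting field data

`two_pass_fit` implements the two-pass workflow for real datasets: S is
first built from the detector envelope plus 2.5 x (pooled telemetry SD),
the model is fitted, S is rebuilt with 2.5 x (posterior mean sigma), and
the model is refitted; density uses the second-pass area. Coordinates are
assumed planar and pre-projected (km for the shipped configuration —
density then reads animals/km^2); no geodesy is performed. The CSV schema
is documented in `gensmr.io`; records whose marked/unmarked status is
unknown have no stream in the data model and must be discarded upstream.

## Problem sizes used in the shipped checks

The packaged test suite runs the four corner cells of the design (nominal
m in {5, 20} x delta in {0, 1}) at 30 replicates per cell with single
chains of 5,000 iterations (1,000 burn-in, 1,000 adaptation), and the
acceptance script recomputes the m=5/delta=0 cell the same way; the full
40-cell, 50-replicate design is available through
`gensmr simstudy` / `run_simulation_study` (resumable via its manifest).
These sizes keep a complete run on one core in the tens of minutes while
holding the Monte-Carlo error of a cell mean near 1.5 animals.

## Known limitations

* Single shared sigma across marking, resighting and telemetry (as the
  model assumes); sex- or behavior-specific detection, density covariates
  and categorical (multi-catch) trap likelihoods are out of scope.
* The marked count must be known; the data model carries no
  unknown-mark-status stream.
* Uniform activity-center intensity over a rectangle; no habitat masks.
* With no telemetry and no spatial recaptures, sigma — and hence density —
  is weakly identified; the initializer refuses to guess sigma in that
  case rather than silently producing a prior-driven answer.
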