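# Methods

This note records the modelling, simulation and numerical choices behind
`nutsurv`, in the spirit of a statistical appendix: what is assumed, what
is tunable, and what the synthetic experiments do and do not establish.

## 1. Outcome definitions

A child is *wasted* if the weight-for-height z-score is strictly below −2,
*stunted* if height-for-age is strictly below −2, and has *low MUAC* if
mid-upper arm circumference is strictly below 125 mm. Boundary values are
non-cases. Z-scores follow the LMS construction
`z = ((x/M)^L − 1)/(L·S)` with the analytic `ln(x/M)/S` limit used for
`|L| < 1e−5`, where the Box-Cox form's O(L) truncation error would exceed
it. Reference tables are user-supplied CSVs (`sex, age_months, L, M, S`);
the package ships no growth reference, and the tables used in tests are
synthetic stand-ins with plausible L/M/S magnitudes, labelled as such.
MUAC is handled in millimetres throughout; values outside [50, 300] mm are
rejected as unit errors rather than silently classified. Missing (NaN)
measurements raise; exclusion is an explicit upstream step, never an
implicit "not a case".

## 2. Regression model

Each indicator is analysed with a separate hierarchical logistic
regression. The linear predictor adds, to the fixed effects
`β'x` (intercept; sex with male reference; age bands 12–23 and 24–59
months with 6–11 reference; the binary child morbidity/vaccination/food
access covariates; household size and under-5 count; maternal MUAC in mm;
EVI, rainfall and temperature as per-cluster values; season as a two-level
factor with Deyr reference):

- a convolution (BYM) cluster effect: an ICAR field `u` on the cluster
  graph plus an exchangeable `v`;
- exchangeable district effects `w`;
- a first-order random walk `t` over survey rounds;
- optionally, second-order random-walk effects over 10 equal-width bins
  for covariates declared nonlinear. These are off by default: per-unit
  odds ratios presuppose linear fixed effects, so the default model keeps
  all reported covariates linear. Interactions are excluded by default.

Identifiability: `u` is constrained to sum to zero within each connected
graph component, `t` and every nonlinear effect to sum to zero overall;
`v` and `w` need no constraint (proper priors). Priors are N(0, 100) on
each fixed effect and Gamma(1, 0.0005) on each precision — diffuse
defaults common in this model family. The log posterior retains the
`(rank/2)·log τ` normalising terms so precision inference is correct; the
ICAR rank is `n − (number of components)`, the RW1 rank `n − 1`, the RW2
rank `n − 2`.

Credible level is fixed at 95%. The reported `OR` is the posterior mean of
`exp(β)` (not `exp` of the posterior mean), with CrI bounds the matching
quantiles of `exp(β)`; percent change is `100·(OR − 1)`.

## 3. Spatial structure

Survey clusters are village points without usable polygons, so the default
neighbourhood is the symmetrised 5-nearest-neighbour graph under haversine
distance (WGS84 lon/lat); Delaunay triangulation and shared-district
adjacency are available alternatives. Disconnected graphs are allowed; the
sum-to-zero constraint applies per component and all rank computations use
the component count. ICAR sampling uses the spectral decomposition of Q
restricted to its positive eigenspace, which lands draws exactly on the
constraint subspace.

## 4. Inference engine

The sampler is a Pólya–Gamma Gibbs scheme: given latent
`ω_i ~ PG(1, η_i)`, the Bernoulli logit likelihood is Gaussian in η, so
**all** location parameters (β, u, v, w, t, f) are updated jointly from
one multivariate Gaussian full conditional, and each precision from its
conjugate gamma full conditional. PG(1, z) variates come from a
numba-compiled implementation of Devroye's alternating-series rejection
sampler (exact; ~0.2 µs per draw).

Numerical details that matter:

- Fixed-effect columns are centred and scaled internally; draws and the
  N(0,100) prior are mapped between raw and scaled parameterisations by
  the exact linear transform, so the target density is identical to the
  documented log posterior.
- The joint Gaussian precision has exact null directions (constant shifts
  of improper-prior blocks that cancel in the likelihood, e.g. `u + c`
  against `t − c`). A ridge proportional to `A'A`, where `A` stacks the
  constraint rows, removes them; because the ridge acts only on the
  constrained directions, the draw — after exact conditioning on
  `Aθ = 0` by kriging — has precisely the constrained target law.
- The centred Gibbs sweep exchanges amplitude between a weak random field
  and its precision very slowly. After each sweep, a joint Metropolis
  rescale move `(x, τ) → (c·x, τ/c²)` per random block proposes that
  exchange directly; each block's prior rank equals its constrained
  dimension, so the acceptance ratio reduces to the likelihood change
  plus `−2a·log c − bτ(c^{−2} − 1)`. Its proposal scale adapts only
  during warmup, as does nothing else post-warmup.
- Default run: 4 chains × 2000 iterations (1000 warmup); a 150-cluster
  (~4600-child) fit completes in about a minute on one CPU.
  Non-convergence (any split-chain rhat > 1.1) is flagged on the result
  and warned, never silent.

A non-augmented adaptive random-walk Metropolis fallback
(`augmentation="metropolis"`) targets the same posterior for
cross-checking, and a Gaussian-likelihood mode exposes the Gaussian-block
machinery to exact conjugate validation. Correctness is defined by
oracles — conjugate closed forms, 1-D quadrature of exact posteriors,
and coverage of generating parameters — not by a specific update scheme.

## 5. Synthetic survey generator

The generator emulates a biannual two-stage cluster design: districts tile
a synthetic 10°×10° region as a grid and are partitioned contiguously into
three zones (NW/NE/SC, cluster shares 22/15/63%); clusters are placed
uniformly within a random district and assigned a livelihood stratum
(agro-pastoral/pastoral/riverine/IDP/urban at 42/27/16/11/4%) and one of 8
rounds alternating Gu (from the first year) and Deyr. Defaults are 1064
clusters × 30 households; each household contributes its under-5 children
(Poisson(2) clipped to [1,4], household-level mean ≈ 2; note the
child-level mean is size-biased upward, as in real surveys), giving
≈ 66,000 children. Households draw size (1 + Poisson(5), mean 6), head sex
(19% female), maternal age (N(31, 7²) years) and maternal MUAC
(N(255, 25²) mm); children draw age uniformly on 6–59 months and binary
covariates at the configured marginals (fever 21%, diarrhoea 17%, ARI 26%,
measles 50%, polio 82%, vitamin A 50%, protein/carbohydrate access 92%,
fruit & vegetable access 41%). Where a marginal was not available
(vitamin A, measles at "about half"), a round default was chosen once.

Environmental surfaces (EVI, rainfall, temperature) are Gaussian processes
with exponential covariance over haversine distance, mapped through the
Gaussian CDF onto bounded ranges (EVI on [0,1]; rainfall on [0,600] mm;
temperature on [18,38] °C — uniform marginals spanning each plausible
range). Correlation ranges are 110/160/220 km. These surfaces reproduce
the *spatial-correlation structure* of remotely sensed covariates, not
their empirical marginals or cross-correlations.

Outcomes: the child's linear predictor η is assembled exactly as in the
model (including ICAR, exchangeable, district, temporal and season terms
drawn from their priors at the configured precisions), and z-scores are
drawn as `z = −2 − Φ⁻¹(expit(η)) + N(0,1)` (MUAC analogously with an
11 mm SD), so that thresholding at −2 (or 125 mm) yields exactly
Bernoulli(expit(η)) outcomes while still producing realistic continuous
anthropometry. The three indicators are conditionally independent given
their linear predictors.

### Calibration defaults

All default effect sizes live in `src/nutsurv/data/defaults.json`, not in
code. The rule: odds ratios that are explicitly reported for this setting
are used verbatim (EVI 0.62/0.51/0.41 for wasting/stunting/low MUAC;
diarrhoea 1.35/1.29/1.20; female 0.73/0.73/1.24); effects reported only
directionally get modest defaults in that direction (e.g. fever ~1.2–1.25,
stunting age bands 2.2–2.3, polio 0.88 for wasting); everything else is
null. Random-effect precisions default to 25 (cluster/district SD 0.2, a
within-cluster ICC of a few percent, typical of nutrition surveys) and 100
for the temporal walk. Intercepts were calibrated once by a logit-shift
fixed point so that pooled prevalences at the full default design match
21/31/36%, and frozen (0.061, −0.579, 1.035).

### What the synthetic experiments show — and what they don't

Passing recovery and calibration tests establishes that the estimator is
correct *under the generating model*: unbiased effect recovery, honest
CrI coverage, and correct prevalence calibration. They cannot establish
robustness to what the generator omits: informative missingness,
displacement and conflict dynamics, intervention placement, measurement
error in anthropometry, non-uniform age structure, or real covariate
marginals and cross-correlations. Single-survey effect recovery at the
150-cluster scale carries sampling noise of several percentage points on
the percent-change scale (for a child-level binary covariate at 17%
prevalence, the information bound alone gives an SD near 10 pp), so
replicate-level summaries are the meaningful calibration check.

## 6. Descriptive pipeline

Prevalences are flagged counts over non-missing counts; children in
clusters without valid coordinates are excluded before spatial modelling
by an explicit operation that reports excluded cluster ids and child
counts and conserves totals. Seasonal averaging partitions months into
Jilal (Dec–Mar), Gu (Apr–Jun), Hagaa (Jul–Sep) and Deyr (Oct–Nov) and
averages within window per year, then across years. Zone-stratified
analysis refits fully independent models per zone (shared ModelSpec, so
covariate rows align); zones under 10 clusters are skipped with a warning.
Records with missing covariates are dropped per model (complete case) with
counts reported.

## 7. Problem sizes used in the shipped checks

The test suite and the acceptance script size their simulations to run
comfortably on a single CPU: reduced surveys (60–150 clusters) for unit
and recovery tests, 20 simulate-and-refit replicates for coverage, 8–50
full-default surveys for prevalence calibration, and 4×2000-iteration
chains for reference fits (shorter chains where only gross behaviour is
asserted). These sizes are the package's reference settings; all of them
are plain parameters and scale up unchanged.

## 8. Known limitations

- The ICAR graph is k-nearest-neighbour by default; polygon adjacency from
  real administrative boundaries is not implemented.
- Weight-for-age (underweight) classification, oedema handling and
  biologically-implausible-z flagging beyond the MUAC unit check are out
  of scope.
- The temporal term is a plain RW1 over rounds; no season×space
  interaction.
- Variance-component posteriors are weakly identified at realistic
  effect sizes with binary outcomes; their chains mix adequately only
  because of the rescale move, and their posteriors remain prior-
  sensitive. Fixed-effect inference is insensitive to this in all checks.
- Zone-stratified fits share no information across zones; small zones
  yield very wide CrIs by design.
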