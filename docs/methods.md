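# Methods

## The statistical model

All models are two-group multivariate-normal structural models on the
per-pair observation vector (both twins' phenotypes, optionally both twins'
polygenic scores). A model is a triple of matrices per zygosity group: a
one-headed path matrix *P* (regressions among latent and observed
variables), a two-headed matrix *S* (variances and covariances of exogenous
terms) and a filter *F* selecting observed variables. The implied covariance
is Σ = F(I−P)⁻¹S(I−P)⁻ᵀFᵀ. Means are fixed at zero throughout because all
phenotypes are residualized for age and sex and standardized before
modelling; a saturated-means variant is deliberately not provided.

The twin design enters through fixed structural constants: additive-genetic
(A) latent factors covary 1.0 across MZ co-twins and 0.5 across DZ co-twins
(random mating, no assortment parameter), shared-environment (C) factors
covary 1.0 within a pair in both groups, and non-shared (E) factors are
independent across co-twins. These constants also scale every *cross-trait*
cross-twin covariance among factors of the same class (e.g. the DZ
cross-twin cross-trait genetic covariance is 0.5·rA). Parameters are shared
across twins (birth-order symmetry) and across groups; equality constraints
are expressed by assigning one parameter object to several matrix cells.

Assumptions inherited from the classical twin design: equal shared
environments for MZ and DZ pairs, no gene–environment interaction or
correlation beyond what the modelled paths carry, multivariate-normal
phenotypes, and random mating.

## Likelihood, fitting, uncertainty

Fitting is full-information maximum likelihood. Rows are grouped by
zygosity and missingness pattern; for each pattern the implied covariance is
subset to the observed entries and the pattern's contribution is
n·(k·log2π + log|Σₖ|) + tr(Σₖ⁻¹·Scatter), with the scatter matrix
precomputed once per pattern, so the cost of one likelihood evaluation is
independent of sample size. Rows with no observed entries contribute
nothing. Missingness is assumed (at least) missing-at-random; the synthetic
generator produces MCAR.

Optimization is bounded quasi-Newton (L-BFGS-B) from the builder's start
values with convergence tolerances gtol = 1e-6 on the projected gradient and
ftol = 1e-10 on the relative −2lnL change, plus up to 10 seeded random
restarts on failure. Parameter values that make an implied covariance
non-positive-definite, or a reciprocal-causation block non-invertible, are
rejected with a large penalty. Path coefficients are estimated
unconstrained (variance shares are squared-and-normalized derived
quantities), which avoids boundary non-convergence; correlation parameters
are bounded to (−0.99, 0.99) and estimates within 1e-6 of a bound are
flagged as boundary solutions.

Standard errors are Wald: the parameter covariance is 2·H⁻¹ with H the
central-finite-difference Hessian of −2lnL (step 1e-5·max(|θ|,1)); a
singular Hessian yields flagged-unavailable SEs rather than numbers.
Confidence statements are therefore Wald/delta-method only;
profile-likelihood intervals are a known omission. Variance-share SEs come
from the delta method applied to h² = a²/(a²+c²+e²).

There is also a covariance-input fit (`fit_covariances`) minimizing the
multivariate-normal deviance Σ n_g(log|Σ_g| + tr(S_gΣ_g⁻¹) − log|S_g| − p),
used for worked examples whose inputs are printed correlation matrices; the
pseudo group size only scales the (unused) uncertainty, not the estimates.

Local identification is checked numerically: the Jacobian of the stacked
unique implied-covariance entries of both groups with respect to the free
parameters (central differences, step 1e-6) must have full column rank,
with singular values below 1e-8 of the largest treated as zero. When
deficient, the null-space basis is reported as parameter combinations. All
tolerances above are function arguments.

## Model-family specifics

* **Latent phenotype factors** (used for the univariate ACE and DoC
  variants with two indicators): one loading fixed to 1 to scale the factor,
  indicator residual variances constrained equal; a single-indicator factor
  has its residual fixed at 0. The saturated correlation, MRDoC and
  cross-lagged families operate on observed scores.
* **DoC**: cross-trait factor correlations are fixed at zero so the causal
  path(s) carry the whole cross-trait covariance. The bidirectional variant
  evaluates the exact (I−P)⁻¹; no series approximation. Direction inference
  is only informative when the traits' modes of inheritance differ — the
  pipeline warns when the traits' h² intervals overlap.
* **MRDoC**: with the pleiotropy path estimated, the residual A and C
  cross-trait covariances are free and the residual E cross-covariance is
  fixed at zero — the constraint under which the causal path remains
  identified alongside pleiotropy. Two corollaries, both verified by the
  identification tests: the causal path leans on the within- vs cross-twin
  E contrast, so near-zero E influence on the exposure drains the design's
  leverage; and a zero instrument path alone does *not* remove algebraic
  identification (the twin contrasts still carry the causal path) — it
  becomes a weak-instrument (power) problem, which the pipeline gates on
  the Wald test of the instrument–exposure path. Because MZ co-twins carry
  identical polygenic scores, the second twin's score is masked for MZ
  pairs (`mask_duplicate_instrument`); otherwise the MZ implied covariance
  is exactly singular.
* **Cross-lagged models**: age-1 phenotypes load on common A/C/E factors
  with free within-time cross-trait factor correlations; age-2 phenotypes
  receive stability paths, the two cross-lagged paths, and fresh residual
  A/C/E factors with free within-time residual correlations. The extended
  model frees four cross-time correlations — age-1 A (or C) factor of one
  trait with the age-2 *residual* A (or C) factor of the other. Cross-time
  confounds attach to residual factors rather than total age-2 factors
  because the age-2 totals already contain transmitted age-1 variance via
  the stability paths; same-trait transmission flows only through
  stability. E cross-time correlations are fixed at zero: freeing them
  makes the rank check fail (rank 26 of 28), reproducing the constraint's
  stated purpose. The age-2 within-time residual correlations stay free in
  the extended model for nesting coherence.

## Comparison, pruning, decomposition

Nested models are compared by χ² difference (Δ(−2lnL) on Δk df) and AIC =
−2lnL + 2k. Pruning fixes *all* non-significant prunable paths (two-sided
Wald p ≥ α, default 0.05) to zero simultaneously — not stepwise — then
refits from the full-model estimates; prunable parameters are the
structural ones (causal paths, cross-lags, stabilities, factor
correlations), never measurement loadings.

The decomposition enumerates treks — Wright path-tracing routes: one-headed
paths traced backward from the first variable, at most one two-headed arc,
one-headed paths forward to the second — and groups them by membership:
contains the direct path; arc is a cross-time A correlation; arc is a
cross-time C correlation; everything else (within-time correlations and
stability). The groups partition the routes (a direct-path trek cannot
carry a cross-time arc; asserted, not assumed), their sum reproduces the
reticular-formula covariance to 1e-10, and percentages are signed — a group
may exceed 100% when another is negative, which matters once negative
cross-lags appear. Percentages are computed on the covariance scale of
standardized variables (identical to the correlation scale when variances
are 1). Decomposition is defined only for recursive models; the
bidirectional DoC is rejected.

## The synthetic cohort generator

`simulate_structural` draws, per pair: A factor vectors (both twins jointly,
cross-twin correlation 1.0/0.5), one shared C factor vector, independent E
vectors per twin, and a polygenic score with cross-twin correlation 1.0/0.5
drawn independently of the trait A factors — so instrument strength and
pleiotropy are direct path coefficients and the fitted MRDoC is correctly
specified. Age-1 scores combine the instrument and age-1 factors with
√share loadings; age-2 scores add stability·age-1 + cross-lag·other-trait
plus residual factors carrying the configured cross-time correlations.
Implied latent covariance blocks are checked for positive semi-definiteness
before any sampling. One integer seed drives a single generator stream in a
documented order (MZ group first: A, C, E, PGS, sex, ages, missingness
mask), so cohorts are bit-reproducible.

Default configuration (one choice, stated here, used unless a test's
scenario dictates otherwise): variance shares a² = 0.3, c² = 0.6, e² = 0.1
for both traits at both ages — illustrative of strongly familial
early-childhood measures where shared environment dominates and non-shared
variance is small; within-time factor correlations rA = 0.35, rC = 0.50,
rE = 0.10; stabilities 0.25; cross-lags 0.10 / 0.11; cross-time confounds
rA = 0.20, rC = 0.35; weak instrument p1 = p2 = 0.05; 2000 MZ and 3000 DZ
pairs; 10% MCAR missingness; small sex (0.10) and age (0.15 per year)
effects on the raw scores, removed by residualization.

What the generator does *not* emulate: skewed or ordinal item scales,
informative (MAR/MNAR) missingness, assortative mating, sex-limitation,
rater/common-method bias, age heterogeneity beyond small jitter, and any
genotype-level structure behind the polygenic score. Passing tests
therefore show that the estimators recover the generating process under the
model's own assumptions — not that those assumptions hold in real cohort
data, where common-method bias alone can inflate shared-environment
estimates.

## Preprocessing

Exclusions are pair-wise: a criterion firing on either twin drops the pair,
and the report counts matches per criterion. Residualization regresses each
phenotype on the covariates plus intercept, pooling both twins' non-missing
observations into one OLS fit (one regression per target); a missing
covariate leaves the target missing rather than imputing; a zero-variance
covariate is dropped with a warning. Covariate choice is per target in the
configuration, since which age accompanies which indicator is a user
decision. Standardization z-scores over the pooled twin-level observations,
so pooled moments are exactly 0/1 while per-column moments are only
approximately so. Sex may arrive in any two-level encoding and is recoded
to {0,1}.

## Problem sizes used by the test suite

Parameter-recovery checks run at 5000 pairs per zygosity group, one seeded
cohort per family, asserting the named structural parameters within 3 SE.
The confound-absorption property uses 100 replicates of 500 + 500 pairs
(zero true cross-lags, rA = 0.4, rC = 0.5), requiring in ≥90% of replicates
that the extended model's cross-lags are within 3 SE of zero while the
naive model's are positive with |z| > 1.96. Calibration checks are scaled
to desk runs: DoC direction recovery 20 replicates at 1500 pairs/group,
null-causal-path Wald calibration 60 replicates at 800, pruning
calibration/power 20/15 replicates at 500. Monte-Carlo moment matching uses
20000 pairs/group with a 4 SE family-wise bound across the ~110 covariance
entries.

## Known limitations

Wald-only inference; no ordinal liability-threshold likelihoods; no
definition variables or moderation; no sex-limitation or rater-bias models;
MCAR-only simulated missingness; no multiple-testing correction across
trait pairings (mirroring common practice of fitting domains separately —
interpret repeated model fits accordingly); the numerical rank check
certifies local, not global, identification.
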