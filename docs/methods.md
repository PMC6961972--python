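# Methods

This note documents the models, numerical choices and known limitations of
the package, in the order data flow through the pipeline.

## Asymmetry scoring

Both fluctuating-asymmetry schemes start from the signed directional
asymmetry `DA = L − R` of a paired region and center it on the sample mean
for that region, so that the *population-typical* lateralization (e.g. the
consistently larger left planum region) does not count as instability.

**Equal contribution.**  Per participant and region the centered deviation
is taken absolute and divided by the participant's own bilateral mean
`(L+R)/2`; the participant's score is the mean over their available
regions.  Dividing before averaging makes each region a unit of equal
weight regardless of its size (a ~720 mm² entorhinal region counts as much
as a ~12,700 mm² superior frontal region), and makes the score
dimensionless and invariant to rescaling any single region's units.

**Proportional contribution.**  Hemispheric totals are formed first and
the total difference `ΣL − ΣR` is the primitive.  The source analyses
state the scheme only up to this subtraction; we mirror the remaining
equal-scheme steps — centering on the sample mean of the total difference,
absolute value, division by the participant's bilateral mean total — so
that both schemes produce non-negative, dimensionless fluctuating
measures that can be correlated with each other.  This is an
interpretation and is flagged as such.  For thickness, the "total" is the
unweighted sum of regional mean thicknesses; a surface-area-weighted total
would be an alternative but is not what a plain reading of "total value"
suggests.

Missing hemispheres: a (participant, region) cell with one side absent is
dropped for that participant only (asymmetry is undefined with one side);
the equal score averages over the remaining regions.  Regions observed in
fewer than two participants are dropped entirely, since the centering mean
does not exist.  Sample means are always computed on the analysis sample
at hand; no external reference means are used.

Subset (P-FIT / non-P-FIT) scores recompute the centering means within the
subset rather than inheriting them, so a subset score is exactly the
full procedure applied to a smaller atlas.  A consequence used as a test
oracle: the region-count-weighted average of the two subset scores equals
the all-region score.

## The measurement model of g

Thirteen tests load on four correlated domains (visuospatial,
crystallised, verbal memory, processing speed), which load on a
second-order g.  Two residual covariances (the two irregular-word reading
tests; the two verbal-recall tests) absorb shared method variance.  The
verbal-memory disturbance is fixed at zero: freely estimated it goes
negative (all verbal-memory variance is shared with g), the classic
Heywood case, and fixing the offending variance at the boundary is the
conventional remedy.  Identification uses the standardized-latent
convention: every latent (residual) variance is fixed at 1 and all
loadings are free, which matches standardized reporting and avoids
marker-variable arbitrariness.

## Estimation

The engine parameterizes the system `v = A v + u`, `u ~ N(M, S)` (RAM
form) and minimizes −2 × the casewise normal log-likelihood; each
participant contributes through the subvector of variables they actually
have (FIML).  Rows are grouped by missingness pattern and reduced to
per-pattern sufficient statistics, so an objective/gradient evaluation
costs a few small matrix operations per pattern.  The gradient is
analytic (chain rule through `B = (I−A)^{-1}`).

Numerical choices:

- **Start values** (fixed, hence deterministic fits): loadings at 0.5 on
  the standardized scale (0.5·sd of the indicator), residual variances at
  half the sample variance, means at sample means, covariances at 0.
- **Preconditioning**: parameters are optimized as θ = D·φ with D the
  parameter's natural data scale (sd ratios for paths, variances for
  variance parameters).  Raw test scales span variances from ~0.006
  (reaction time in seconds) to ~300 (memory sums); without this the
  quasi-Newton Hessian is hopelessly ill-conditioned.  Preconditioning
  changes nothing semantically — equality constraints remain constraints
  on raw coefficients.
- **Convergence**: L-BFGS-B with ftol 1e-14 and gradient tolerance 1e-6,
  restarted with a fresh Hessian approximation if the line search stalls;
  a fit is accepted when the preconditioned gradient-infinity-norm is
  below 1e-2 on the −2logL scale (parameter error orders of magnitude
  below reporting precision), otherwise a convergence error is raised.
- **Variances are unconstrained** (may go negative) rather than
  log-parameterized.  This is deliberate: Heywood detection requires
  observing the inadmissible negative estimate (with a true boundary
  variance the unconstrained estimate is negative with probability ≈ ½),
  and `heywood_refit` then fixes the most negative variance at zero and
  refits until admissible.  Non-positive-definite implied covariances
  during line search get a finite penalty value.
- **χ² convention**: the likelihood ratio against the saturated model
  (free mean vector and covariance matrix), whose FIML solution is closed
  form with complete data and obtained by EM otherwise.  With complete
  data this equals n × the classical ML discrepancy (not n−1); the
  convention is documented here because the original software's choice is
  not recoverable, and consequently exact equality of AIC/BIC with any
  published values is not claimed.  Means are always modelled (required
  by FIML and invariance testing).
- **Fit indices**: CFI and TLI against the independence baseline (free
  per-variable means and variances, closed-form FIML solution);
  RMSEA = sqrt(max(χ²−df, 0)/(df·(n−1))); SRMR uses covariance residuals
  only (no mean residuals), standardized by the saturated SDs, including
  the diagonal, n-weighted across groups.
- **Standard errors**: inverse observed information, with the Hessian
  obtained by central differences of the analytic gradient.  Standardized
  coefficients are rescaled point estimates; their SEs are not
  delta-method-corrected for the standardization (raw SEs are reported
  alongside).
- **df** = p(p+3)/2 × groups − free parameters, mean structure included.

Equality constraints are implemented by parameter sharing (one underlying
parameter), not penalties.  Nested comparisons use Δχ² = difference of the
two likelihood-ratio statistics; Δdf must be positive, and a constrained
model fitting better than its parent by more than 1e-6 raises rather than
silently clipping.

**Measurement invariance.**  The configural model frees all measurement
parameters per group (latent variances 1, latent means 0 in every group);
the strong model equates loadings and intercepts across groups and in
exchange frees latent variances and means in the non-reference groups.
The reported test is strong against configural.  Type-I error of this
test and of the equality-constraint tests is verified by simulation in
the acceptance suite (200 replicates at reduced scale: one-factor models,
n = 150–200, chosen to keep the whole suite inside a desktop test budget;
the rejection-rate band is ±3 Monte-Carlo SEs around the nominal 5%).

## Structural models

Asymmetry predictors enter the structural models z-scored, so equality
constraints on their paths compare effect sizes rather than slopes on
score-specific scales, and standardized and raw coefficients coincide up
to the model-implied sd of g.  The three (or six, in the P-FIT model)
predictors are exogenous and freely correlated — a saturated block whose
implied moments reproduce the sample moments.

Per-region association models are fitted one region at a time (the
region's normalized absolute asymmetry as the single predictor of g):
102 coefficients from a joint model would not be identified at cohort
scale.  Raw p-values are reported with a Bonferroni column added for
reference but not used for gating.

**Mediation.**  The SES factor is measured by four indicators
(people-per-room, toilet type, people sharing a toilet, father's
social class on the 1–5 occupational scale) with a residual covariance
between the two toilet-related indicators; `heywood_refit` handles the
people-per-room residual, which sits at the boundary in the default
generator.  Paths: SES → mediator (a), mediator → g (b), SES → g (c′).
The indirect effect is a·b with a delta-method SE from the parameter
covariance; attenuation% = 100·(total − direct)/total = 100·ab/(c′+ab) on
unrounded standardized estimates.  Sex-stratified structural models are
deliberately not fitted: strong invariance across sex is testable (and
fails by construction when group offsets are configured), after which a
pooled-sex latent comparison would not be meaningful.

## Bayes-factor correlations

BF10 = ∫ f(r | ρ, n) π(ρ) dρ / f(r | 0, n) with f the exact (Hotelling)
sampling density of the Pearson correlation, computed stably in log space
with the Gaussian hypergeometric term, and π a stretched
Beta(1/κ, 1/κ) prior on (−1, 1).  Quadrature is composite Simpson on an
open grid of 4001 points; the tests require agreement with a 200k-point
trapezoid oracle to 0.5% and stability to grid halving at 1e-4.  The
default κ = 1/3 is the conventional "medium" prior width; because the
original analyses do not state their prior, published BF magnitudes are
treated as directional, not numeric, targets.  Factor scores for g use
the regression (Thomson) estimator from the model-implied joint moments,
evaluated on each participant's observed indicator subvector.

## The synthetic cohort

The generator emulates: positive region sizes spanning ~700–13,000 mm² of
(bilateral) surface area with the superior-frontal/entorhinal ratio
anchored at 12,730.15/722.90; small region-specific directional
asymmetries (0.2–2.5% of size, alternating sign); fluctuating deviations
per region with sd = 4% of region size, scaled per participant by
exp(λ·D) with D ~ N(0,1) a latent developmental-instability factor
(λ = 0.08 by default, chosen so the three cortical asymmetry scores
inter-correlate near 0.3, the modest coupling the analysis design
implies); a g built from the realized z-scored asymmetry scores with
standardized coefficients (−0.03 surface area, +0.07 volume, −0.18
thickness, 0 FA) plus a −0.29 SES path and a unit-variance-preserving
disturbance; the hierarchical battery with published test means/SDs; and
MCAR missingness at 2% per cognitive/SES cell.  n = 636 by default.

Because g is assembled from the *realized* scores, the structural
coefficients are exact in-sample population values and the fitted model is
correctly specified, which is what makes the 100-replicate recovery check
a clean bias test (mean standardized thickness path within ±2 Monte-Carlo
SEs, ≈ ±0.01, of −0.18).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: spatial covariance between neighbouring
regions, scanner artefacts and site effects, age heterogeneity,
non-normal test distributions, MAR/MNAR missingness (FIML correctness is
only exercised under MCAR), truly ordinal SES indicators (toilet type and
father's class are discretized, mildly attenuating their loadings), and
reaction-time tests are generated already oriented (higher = better) —
on real data the reader's orientation flag must be used.  The
instability→asymmetry coupling has no published effect size; the default
is a design choice, not an estimate.

## Limitations

- No robust or weighted estimators (MLR/WLSMV), ordinal thresholds, or
  bootstrap SEs; multivariate normality is assumed throughout.
- The equality of AIC/BIC/df with published tables is not claimed (mean
  structure and χ² multiplier conventions differ across software).
- One printed nested-test row in the source tables (Δχ² = 0.02 with
  p = .896) is internally inconsistent at three decimals — χ²₁ upper tail
  at 0.02 is .888 — presumably because Δχ² was rounded for printing; it is
  therefore documented here and excluded from exact-arithmetic checks,
  which use the four self-consistent rows.
- Proportional-method post-processing beyond the total subtraction is an
  interpretation (see above).
- Whether the original per-region models included other regions as
  covariates is unstated; separate single-predictor models are fitted.
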