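# Methods

## Scope and estimand

The package estimates the association between residential greenness
(NDVI tertiles 2–3 vs 1, assigned within community type) and four birth
outcomes — preterm birth, small for gestational age (SGA), low 5-minute
Apgar score, and term birth weight — in cohorts spanning city, borough
and township communities. The estimand of the binary-contrast models is
the covariate-conditional odds ratio (grams difference for weight) on the
common-support-restricted population. Positivity failures are handled by
(a) stratifying every stage by community type and (b) trimming each
stratum to propensity scores between the 1st percentile among the exposed
and the 99th percentile among the unexposed.

## Exposure model

Seasons are meteorological (winter = December–February, with December
assigned to the winter labelled by the following January). A birth in the
first half of its season (the midpoint day inclusive, computed on actual
calendar lengths) receives the three prior seasons; a birth more than
halfway through receives the two prior seasons plus the season of birth.
Buffer membership is centre-distance ≤ radius, inclusive, with the home
pixel always included, so on a 250 m grid the 250 m buffer is the 5-pixel
plus shape around a pixel-centre home. The buffer summary is the pooled
mean over (cell, composite) pairs — missing cells drop out of numerator
and denominator — or, for the max variant, the maximum over composites of
per-composite buffer means. Tertiles and percentiles use
linear-interpolation empirical quantiles everywhere (exposure cutpoints,
the 20th-percentile sensitivity cutpoint, growth-reference percentiles,
trim bounds); boundary values fall in the lower tertile, while the
percentile dichotomization uses ≥ threshold.

## Outcome derivation

The exclusion cascade counts one reason per record in a fixed priority
order (linkage, geography, plurality, stillbirth, defects, weight < 500 g,
gestational age < 22 weeks). The SGA reference is internal: 10th
percentile of birth weight per (sex, completed week) cell of the included
cohort, minimum cell size 20 with nearest-week pooling, and an upward
monotonicity repair across weeks (both logged). "Below the 10th
percentile" is read strictly: a birth exactly at the percentile is not
SGA. Gestational age is continuous for the preterm cutoff (< 37.0) and
completed weeks for the reference.

## Propensity scores and trimming

The super learner uses exposure-stratified V-fold cross-validation
(V = 10 by default; V = 5 in the replicate studies), binomial negative
log-likelihood as the loss (the spec-level phrase "prediction error" is
not a named loss; log-loss is the natural choice for probabilities), and
SLSQP on the simplex with tolerance 1e−8, polished from the best vertex
whenever the solver leaves slack, so the ensemble risk provably never
exceeds the best learner's. Ties between learners with identical
prediction columns are split uniformly. Final scores are the weighted
full-sample refits, clipped to [1e−4, 1−1e−4]. A learner that fails on
any fold is dropped with a warning. The default library is intercept-only,
L2 logistic, spline-expanded logistic (a GAM surrogate; cubic splines with
4 knots on columns with > 4 distinct values), and depth-2 gradient-boosted
trees.

Trimming uses the propensity fit from the full pre-trim community-type
sample (single estimation pass; scores are not re-estimated after
restriction) and inclusive bounds. Under identical score distributions the
rule removes ~1% of each group at its own bound and ~1% more at the other
group's bound; `TrimBounds` reports both decompositions. In the synthetic
cohorts trimming removes more of each stratum (~30–45%) than the
motivating study reported (~25% in cities): season of birth predicts the
windowed NDVI summary sharply, so propensity scores are better separated
than in real data. This matters for interpreting retained sample sizes,
not for the estimand.

## Regression and inference

Adjusted models follow a fixed covariate set: sex, year band, season of
birth, maternal age (linear + quadratic, centred at the sample mean),
race/ethnicity (3-level: white, black, Hispanic, with the rare residual
level merged into the reference), primary-care status, smoking, BMI class
(18.5/25/30 boundaries), parity, Medical Assistance, antibiotic orders,
road distance, water source, wells within 20 km, AFO exposure,
walkability, deprivation quartile, and delivery hospital; the birth-weight
model adds gestational age. Standard errors are a one-way clustered
sandwich at the community level — the coarsest level of the
neonate-in-mother-in-community nesting; mother-level clustering is
available via the spec's `cluster` field — with t(G−1) critical values,
the standard small-sample practice for few clusters. Likelihood-ratio
tests (ML fits on identical rows, χ² reference) drive the greedy forward
interaction screen (declared order, p < 0.05) and the
quadratic/cubic nonlinearity checks of the continuous-NDVI model (scaled
per 0.1 NDVI). Quasi-separated cells of categorical adjustment covariates
(levels with zero or all events, which arise in trimmed strata) are
collapsed into the variable's largest regular level before fitting and
recorded in the model audit; genuine separation still raises an error
naming the covariate. The residual semivariogram subsamples pairs above
200,000 and flags empty bins.

## Synthetic-data generator

The generator is first-class code defining the study conditions:

* **Region.** Communities are axis-aligned square blocks (12 × 12 pixels
  of 250 m) on a planar grid: 24 city, 30 borough, 40 township
  communities with 3,400 / 4,700 / 8,800 raw births (16,900 total,
  matching the scale of the motivating post-exclusion cohort; community
  counts are scaled down ~5× from the motivating geography to keep a
  full run around half a minute). Replicate studies use a city-only
  region (24 communities, 2,500–3,000 births).
* **Raster.** NDVI = type base (city 0.45 < borough 0.51 < township
  0.56) + per-community offset (SD 0.045) + smooth within-community
  field (coarse Gaussian noise, bilinear upsampled, SD 0.03) + a summer-
  peaking sinusoid (amplitude 0.16, peak at day 196) + per-composite
  noise (SD 0.012), clipped to [−1, 1]. These values reproduce the
  observed orderings: within-type tertile cutpoints land within ~0.01 of
  the motivating cohort's 0.43/0.49/0.54, and city zones are less green
  than townships.
* **Confounding.** A latent place-based disadvantage L =
  −c·z(local static NDVI) + N(0, 0.8), with c the `confounding_strength`
  (default 1), tilts Medical Assistance, smoking, race mixture, BMI and
  age. Outcomes depend on L **only through the measured covariates**, so
  the adjusted model is correctly specified and the built-in effects are
  recoverable; the season-of-birth/NDVI association arises mechanically
  from the seasonal window rule.
* **Outcomes.** Binary outcomes are logistic in the measured covariates,
  the true per-type exposure effects (defaults: city preterm OR 0.78,
  SGA OR 0.73, null Apgar, +42 g term weight; null outside cities), a
  small community intercept (SD 0.06), and an intercept calibrated by
  root-finding to marginal prevalences 11.5% (preterm), 10% (SGA), 2%
  (low Apgar). Gestational age is drawn conditional on the preterm flag
  (37 − gamma(1.5, 1.9) − 0.15, floor 22.05; truncated normal 39.35 ±
  1.15 for term). Birth weight follows a piecewise-linear median curve in
  completed week (female ×0.96) plus covariate effects, the exposure
  effect, and week-dependent noise; within each (sex, week) cell, weights
  are swapped so SGA-flagged births occupy the bottom ranks, keeping the
  planted flags consistent with the downstream empirical-percentile
  classification up to binomial boundary churn.
* **Exposure ground truth** is computed with the package's own exposure
  code on the post-exclusion sample, so the generator's exposure and the
  pipeline's agree exactly.
* **Structural violation.** When enabled, 35% of city tertile-1 births
  form a "subsidized housing" stratum with exposure probability exactly
  zero, an extreme measured profile (Medical Assistance, smoking,
  elevated antibiotics, very low prenatal visits ~ Poisson(2) vs 10), and
  a direct outcome log-OR of 2.0. Prenatal visits sit in the propensity
  covariate list but not in the outcome adjustment set — the lists differ
  exactly this way in the motivating design — so the stratum is visible
  to the propensity model (the boosted trees isolate the cell) but not
  absorbable by the outcome model. This is what makes the untrimmed
  estimate biased and the trimmed one nearly unbiased.
* **Reproducibility.** One global seed with named substreams per layer
  (raster noise, mothers, covariates, outcomes, …), so any stage can be
  regenerated in isolation, bitwise.

### What the generator does not emulate

Real geographies and projections, MODIS QA/cloud masking, address
mobility during pregnancy, spatially autocorrelated unmeasured risk
factors, EHR missingness mechanisms (missingness is absent by default),
and within-mother outcome correlation beyond shared covariates and
address. Passing tests therefore demonstrate the pipeline's correctness
and its operating characteristics under the stated generating model, not
robustness to those real-data features.

## Replicate studies and problem sizes

`greenbirth.studies` packages the verification experiments at desk scale:

* **Recovery:** 200 replicates, 2,500 city births, V = 5, two-learner
  library (intercept + logistic; the generator's exposure model is
  logistic, so the heavier library adds runtime, not information).
  Medians recover the built-in ORs to well within ±0.05 and CI coverage
  is ~94%.
* **Null calibration:** with every true effect zero, the exposure test
  rejects at ~5% (150 replicates) on the well-powered preterm outcome.
  The same check on the ~2%-prevalence Apgar outcome (~50 events against
  ~25 parameters) is anticonservative (~10%) — the familiar rare-event
  Wald phenomenon, which the motivating study's city Apgar model (~58
  events) would share. Conclusions about rare outcomes at this scale
  should rely on likelihood-ratio or exact methods.
* **Structural confounding:** 100 replicates at 3,000 births with the
  violation enabled; the trimmed estimate beats the untrimmed on
  absolute bias in ≥ 90% of replicates (untrimmed bias ≈ −0.4 log-OR,
  trimmed ≈ −0.1).
* **Super-learner checks:** 50 synthetic logistic datasets (n = 400);
  risk gap ≤ 0 to 1e−6 and weights within 0.01 of a 0.001-step grid
  search.
* **Trimming oracle:** 1,000 random instances against a five-line
  sort/percentile/filter oracle.

## Known limitations

Cluster-robust inference with ~24 communities is adequate but not exact;
CR2-type corrections are not implemented. The interaction screen is
greedy in declared order (full enumeration is exponential). The growth
reference's monotonicity repair can inflate SGA rates if the true weight
curve is flat across weeks (not the case for realistic curves). The AFO
metric's functional form (Σ AU/d², km, 0.1 km distance floor) is one
reasonable convention among several; it is logged in the covariate audit.
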