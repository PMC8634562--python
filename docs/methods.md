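# Methods

`lifetraj` models a life-course outcome trajectory (weight in kg from
birth to early adulthood) by pooling longitudinal data from several
cohort studies that each cover only part of the age range.  This note
documents the statistical model, the algorithms, the synthetic data
the package validates itself on, and the design decisions taken where
more than one reasonable choice existed.

## The analysis model

For child *i* with weight measurements *y*<sub>ij</sub> at ages
*t*<sub>ij</sub>, the model is a 2-level linear mixed model
(measurements nested in children):

    y_ij = x_ij' beta + z_ij' b_i + e_ij,
    b_i ~ N(0, G),    e_ij ~ N(0, sigma^2(t_ij)),

where

* the fixed design **x** contains an intercept, the nonlinear age
  basis, cohort indicators (optionally crossed with every basis
  column, so each cohort can bend the curve), and child-level
  covariates (sex, ethnicity, parental education), again optionally
  crossed with the basis;
* the random design **z** is the intercept plus all basis columns,
  with an unstructured child-level covariance `G` — children differ in
  both level and shape of growth;
* the residual variance `sigma^2(t)` is *not* constant: weights at 18
  scatter far more than birth weights.  Two structures are available,
  both with zero covariances between the measurement-level effects:
  **segmented** (one variance per age band; default a single cut at 2
  years) and **age_linear** (independent measurement-level intercept
  and age slope, giving `s0 + s1 t^2`).

Cohort enters as a fixed, not random, level: with only a handful of
cohorts a third random level cannot support reliable variance
estimation, so each cohort receives its own fixed offset (and
optionally its own basis interactions).

### Age bases

*Fractional polynomials* of degree 1-2 over powers
{-2, -1, 0, 0.5, 1, 2, 3}, with `t^0 = ln t` and the repeated-power
rule `(p, p) -> (t^p, t^p ln t)`.  The canonical candidate space has
7 + C(7,2) + 7 = 35 members.  Because ages start at 0, any spec
involving a logarithm or negative power applies an `age_shift`
(default 1 year) before transforming; the shift is recorded in the
spec and therefore in every serialized output.

*Restricted cubic splines* with 3-7 knots at Harrell's percentile
placements (e.g. 10/50/90 for 3 knots), using the truncated-power
basis normalized by (k_K - k_1)^2 so coefficients stay on comparable
scales.  The basis is linear outside the boundary knots and twice
continuously differentiable everywhere; both properties are asserted
numerically in the test suite.  Knot percentiles are computed on
measurement-level ages (children with more visits weigh more heavily),
and during model selection on the selection sample only, so validation
stays untouched.

### Estimation

Children are independent, so the marginal covariance is block
diagonal: `V_i = Z_i G Z_i' + R_i` with diagonal `R_i`.  The engine
maximizes the exact profiled ML or REML log-likelihood:

* fixed effects are profiled out by GLS at each variance-parameter
  value;
* `G` is parameterized by its log-Cholesky factor and the level-1
  variances by their logs, making the problem unconstrained with
  positive-semi-definiteness by construction;
* per-child linear algebra uses the Woodbury identity, so cost is
  linear in measurements and cubic only in the number of random
  effects (at most 8 here); children with equal visit counts are
  processed as batched tensors;
* gradients are analytic (the envelope theorem removes the beta
  terms); optimization is L-BFGS-B after a short EM warm start, whose
  steps are cheap and move variance parameters in large stable jumps.
  The random-effect design is standardized internally during
  optimization (G is mapped back afterwards) for conditioning.

Numerical choices: relative function tolerance 1e-9 by default
(selection uses 1e-8 with capped iterations, see below); `converged`
requires a relative working-scale gradient below 1e-4; log-variances
are bounded away from overflow (roughly e^-7 to e^12 on the variance
scale).  REML is the default — ML variance components are biased
downward, and the suite checks the REML >= ML ordering on average.
Aliased fixed-effect columns (identically zero, or linearly dependent
— e.g. a cohort whose whole age window lies beyond three knots, where
truncated cubics collapse to plain cubics) are detected by pivoted QR
and dropped, mirroring the exclusion of interactions the data cannot
support; dropped names are recorded and respected by prediction.

Exact ML and REML values are verified against a naive dense
multivariate-normal implementation to 1e-8 on random small instances,
and the homoscedastic random-intercept subcase against both the
balanced-ANOVA closed form and statsmodels MixedLM.

### Prediction

Mean trajectories are `x(t)' beta` with delta-method 95% intervals
(normal quantiles); contrasts are differences of two covariate
patterns at one age.  Because cohorts cover different age ranges, the
model is never used to predict outside the observed support of the
pattern's cohort: such requests raise unless explicitly overridden.

## Two-stage model selection

Selecting among 40 candidates on the full pool is wasteful and
selecting per cohort is biased toward simple shapes, so selection runs
on a cohort-stratified random sample of children (default 15,000;
largest-remainder rounding keeps cohort shares to within one child).

* **Stage 1** (trajectory form): every FP and RCS candidate is fitted
  by ML with the stage-1 structure — intercept + basis fixed effects
  (plus cohort main effects by default; full cohort interactions are
  restored for the final model), full random effects, and two
  independent measurement-level variances for ages <=2 and >2 years.
  Candidates near the top of their family's criterion ranking that
  have not converged under a capped iteration budget are re-polished
  from their own warm start with a full budget, so the shortlist (the
  best `top_k`, default 2, per family by the criterion — default BIC,
  AIC also reported) compares settled optima.  The shortlist is then
  adjudicated on the validation children by fixed-effects-only MSPE
  under the **one-standard-error rule**: among shortlisted candidates
  whose MSPE lies within one paired standard error of the minimum
  (the SE of the mean per-measurement squared-error difference
  against the minimizer), the most parsimonious wins; remaining ties
  break to canonical candidate order.  The 1-SE refinement matters
  because a flexible spline and a well-chosen fractional polynomial
  often predict near-identically — raw argmin adjudication would
  choose between statistically indistinguishable candidates by noise,
  while genuinely better families win by margins that are orders of
  magnitude larger than the SE.
* **Stage 2** (level-1 structure): the winning trajectory is refitted
  by REML under each level-1 candidate (default: segmented with a cut
  at 2 years, and age_linear); REML-based criteria are valid here
  because the fixed effects are identical across candidates.

ML is used whenever candidates differ in fixed effects (stage 1), REML
when only covariance structures differ (stage 2).

The *summed-likelihood* alternative — fit the same model per cohort
and add the log-likelihoods — is implemented for comparison and raises
a structural error for splines whose knots fall outside any cohort's
age range, which is precisely why the random-sample route is the
primary procedure.

*Interaction pruning*: for each covariate level and basis column, the
package counts children and measurements inside the column's active
region (for spline column *j*, ages above knot *k_j*; FP columns span
the whole range).  Interactions below configurable thresholds
(defaults: 30 children, 100 measurements) are dropped and logged — the
rule formalizes the exclusion of, e.g., an ethnic group observed only
in an early-childhood cohort crossed with spline terms that act only
at older ages.  Cohort x basis interactions are pruned by the same
rule.

## Missing data

**Outcomes are never imputed.**  The likelihood uses all observed
measurements and is valid when missingness depends on observed data
(MAR); the suite verifies that deleting half the measurements at
random moves fixed effects by less than sampling noise.

**Child-level categorical covariates** (ethnicity, maternal education,
paternal occupation) can be missing sporadically or systematically
(never measured in a cohort).  The package implements an iterative,
trajectory-summary multiple-imputation procedure:

1. initialize missing values from observed within-cohort category
   frequencies (pooled frequencies where a cohort observed none);
2. fit the full analysis model — interactions included — to the
   current completed data;
3. for each incomplete covariate, compute each child's
   empirical-Bayes trajectory summaries **with that covariate's own
   fixed-effect contribution folded back into the residual** (its
   coefficients are zeroed before the BLUP pass).  This matters: the
   plain EB residuals are computed *after* the covariate's effect, so
   among covariate-observed children they carry no information about
   it, and imputation would collapse to frequency draws (validation
   showed exactly this attenuation before the fold-back was added).
   With the fold-back, the summary is the child's outcome location
   unexplained by everything except that covariate — the statistic
   that predicts it, and no circularity arises because it derives
   from the observed outcomes, not the imputed category;
4. regress the covariate on the other covariates, cohort indicators
   and the summaries (multinomial logistic with a small ridge;
   separation triggers a stronger ridge with a warning), draw
   coefficients from their asymptotic normal distribution, and draw
   the missing categories;
5. repeat 2-4 for `n_cycles` (default 10) and return the completed
   data.  `M` (default 25) independent runs give the imputations,
   pooled by Rubin's rules (within-variance W, between-variance B,
   total T = W + (1+1/M)B, Satterthwaite-style df, t intervals).

For a systematically missing covariate, the affected cohorts'
indicators are dropped from that covariate's imputation model (they
are unidentifiable there), so the covariate-summary relationship is
borrowed from the cohorts that observed it — the only identifiable
MAR-consistent choice.  Whether parameter draws should come from the
asymptotic normal or a bootstrap is a genuinely open choice; the
asymptotic route was chosen for speed and determinism.  Ethnicity in
single-ethnicity cohorts is a harmonization constant, not an
imputation target.

## The synthetic cohorts

No public data exist for the motivating application, so a first-class
generator produces data with the exact structure the analysis assumes:
per-cohort age windows, visit schedules with Gaussian jitter truncated
to the window, geometric per-visit dropout (monotone exit; the first
visit is always recorded), optional late entry for school-type
cohorts, covariates drawn from per-cohort distributions, systematic
missingness by blanking whole covariates, and sporadic MAR missingness
that is logistic in a per-child outcome summary.  The shipped
five-cohort design mirrors the published structure: windows 0-20,
0-5, 0-6, 9-18 and 0-16 years; median measurements per child from ~5
to ~57; one single-sex cohort; maternal education never measured in
the two oldest cohorts; a South-Asian-majority inner-city cohort.
Dropout hazards are free parameters of the generator, not calibrated
values — the real cohorts' dropout mechanisms are unpublished.

The default generating truth anchors the fixed effects to a reference
weight-for-age curve (3.5 kg at birth to ~65 kg at 20 years) by
least-squares projection onto the chosen basis, sets the child-level
intercept SD to 1 kg with trajectory-coefficient SDs calibrated so
each basis term contributes ~0.6 kg RMS deviation, and uses segmented
level-1 variances of 0.09 kg² below age 2 and 2.25 kg² above.

What the generator does *not* emulate: multiple births, measurement
source heterogeneity (clinic vs parental report), secular calendar
trends, and real-world coding messiness beyond the mapping-table
mechanism.  Passing tests therefore demonstrate internal validity of
the machinery under the assumed model, not robustness to those
real-data features.

## Validation studies and problem sizes

`lifetraj.studies` fixes the desk-scale designs used by the test suite
and by `scripts/acceptance.py`:

* likelihood-oracle agreement on 25 random instances of <=5 children
  x <=6 visits;
* REML recovery over 20 replicates of the five-cohort design scaled
  to 2,000 children (every parameter within 3 Monte-Carlo SEs);
* trajectory-family selection with n_select = 1,500 over 10 replicate
  seeds per generating family (5-knot RCS and FP(0,1)), with stage-1
  fits capped at 30 quasi-Newton iterations after 6 EM steps — the
  family decision is made at stage 1, and observed between-family
  criterion gaps exceed the capping error by two orders of magnitude;
* MI validity at 800 children with M = 5 and 3 cycles: MCAR (20%)
  pooled estimates within 3 SE of the full-data fit, and the
  outcome-dependent MAR head-to-head against complete-covariate
  analysis over 12 seeds.  The MAR mechanism uses an age-adjusted
  outcome proxy (mean deviation from pooled age-bin means) — a raw
  mean-weight proxy is dominated by which ages a child happened to be
  measured at, not how heavy they run.

These sizes are the package's own validation defaults, chosen so the
whole suite runs on a single laptop core in minutes; all of them are
arguments and can be scaled up.

## Known limitations

* The optimizer can settle in local optima for severely misspecified
  candidates (flat, multimodal profiled surfaces); this does not
  affect family-level selection, where criterion gaps are large, but
  per-candidate log-likelihoods for poor candidates should not be
  over-interpreted.
* Contrast intervals after MI use the pooled total covariance with
  normal/t quantiles; no small-sample refinement beyond Rubin's df is
  applied.
* The imputation model is multinomial-logistic in the EB summaries;
  strongly non-logistic covariate-outcome relationships would be
  approximated, not captured.
* Sandwich/robust standard errors, GEE-style marginal models, and a
  third random level for cohorts are deliberately out of scope.
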