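# Methods

## Exposure model

The exposure source of record is an annual panel: one mean concentration per
(zip code, calendar year, constituent), in µg/m³ for elemental carbon,
ammonium, nitrate, organic carbon, sulfate and total PM₂.₅ and ng/m³ for the
ten trace constituents. Individual exposure is the 1-year pre-transplant
moving average with weight `tx_month/12` on the transplant year and
`(12 − tx_month)/12` on the year before. Conventions adopted where the
formula alone does not settle them:

- The transplant month counts fully toward the transplant year, so January
  gives weights 1/12 and 11/12 (not 0 and 1); this is the only convention
  consistent with July → 7/12.
- Whether the window excludes the transplant month itself is ambiguous; the
  worked 7/12–5/12 example is followed literally.
- Missing (zip, year) panel rows are never interpolated. The linkage policy
  is `drop` (exclude the recipient, log the count) or `strict` (abort);
  the default is `drop`, mirroring exclusion rather than imputation of
  incomplete records.
- Zip codes are opaque strings; leading zeros are preserved end to end.

The output is a convex combination, so it is bounded by the two annual
values and is non-decreasing in transplant month whenever the transplant
year's level exceeds the prior year's (both property-tested).

## Decile scoring

Each constituent is scored 0…q−1 (q = 10) against empirical quantile cut
points with right-closed bins: a value equal to a cut point falls in the
lower bin, which makes scoring deterministic under ties. Cut points are
estimated once on the full analysis sample, before the train/validation
split, so that "one decile" means the same concentration step in both
halves; they are frozen in the fitted transformer and applied unchanged to
new data. A constant column cannot be ranked: it scores 0 everywhere and is
flagged as degenerate rather than failing the run.

## Two-stage WQS estimation

Recipients are split at random into a training fraction (default 0.40, a
conventional choice for this family of mixture models; the split ratio is
exposed as a parameter) and a validation remainder. Stage 1 maximises the
Bernoulli likelihood of the outcome over the weight simplex jointly with
unconstrained intercept, index coefficient β₁ and covariate coefficients.
The simplex is handled by a softmax reparameterisation optimised by L-BFGS
with analytic gradients from five starts (one uniform-weight start plus four
random), followed by an SLSQP polish in the direct (w, β) parameterisation
with explicit bounds and the sum-to-one constraint. The polish matters:
softmax cannot represent boundary optima (weights exactly 0) at finite
parameter values, and likelihood maxima on a simplex face are common; the
polished solution matches an exhaustive 0.02-resolution simplex grid search
to ~1e-13 on seeded test datasets. Objective tolerance is 1e-8; a fit that
converges from no start is flagged and that bootstrap sample is skipped and
counted.

Stage 1 is repeated on B = 100 bootstrap resamples drawn with replacement at
the recipient level (whole person-month blocks for survival outcomes), and
the converged weight vectors are averaged unweighted and renormalised — the
plain mean, with a |β₁|-weighted mean available behind a flag as a
sensitivity variant. Covariates are included in stage 1 as well as stage 2
by default (`adjust_stage1`), consistent with a stage-2 model that carries
βz′Z; a flag turns stage-1 adjustment off.

Stage 2 freezes the averaged weights, computes wqs = Σ wᵢdᵢ (bounded in
[0, 9]; increasing one constituent's decile by 1 moves the index by exactly
wᵢ), and fits the validation-split GLM. Confidence intervals are Wald at
95%; effects are reported both as exp(β₁) and as the percent change
(exp(β₁) − 1)·100 with CI endpoints transformed identically. Suspected
separation (very large standard errors) is flagged with advice rather than
silently reported. One top-level seed fans out deterministically
(`numpy.random.SeedSequence`) to the split, the bootstrap resamples and the
optimiser starts.

## Discrete-time survival

Follow-up of T months becomes T person-month rows, t = 1…T, with the event
indicator 1 only in the final row of a recipient whose event occurred;
administrative censoring is applied at 60 months, and a first-year
sensitivity refit truncates the table at t = 12, converting later events to
censorings. Same-month event and censoring resolves to the event. Death
censors the graft-failure stream at the death month in the synthetic
generator, matching a death-censored graft-failure outcome.

The pooled logistic model regresses the monthly indicator on wqs, covariates
and a natural cubic spline in t. The model is fit in the event direction
(P[Yₜ = 1 | at risk]); the equivalent survival-direction parameterisation
differs only in coefficient signs, and reporting uses the hazard direction
so aHR > 1 means harm. The spline basis is the truncated-power natural
construction — df columns, linear beyond the boundary knots (min/max
observed t), interior knots at equally spaced quantiles of observed event
months; df = 4 by default, configurable. The basis spans the same column
space as R's `splines::ns` with matching knots (verified against frozen
reference values to 1e-8). Wald variances from the pooled fit are used
without within-recipient clustering correction; with one time-fixed exposure
and at most one event per recipient this is the standard choice for this
model, and it is a known limitation.

With small monthly risks the pooled-logistic odds ratio approximates the
continuous-time hazard ratio. The acceptance check simulates exponential
event times (constant monthly hazard 0.004, per-decile HR 1.05, n = 4000,
administrative censoring at 60 months), discretises to months, and finds
mean relative bias of the log-aHR below 5% over 100 seeded replicates —
a genuine discrete-vs-continuous comparison, not a refit of the generating
model. An independent Cox fit (lifelines) on the same data agrees with the
pooled-logistic estimate in a cross-check test.

## Effect modification

A binary modifier enters stage 2 as a main effect plus a wqs×modifier
product, with stage-1 weights left frozen (weights are estimated once on the
full training split, not per subgroup). The reference-subgroup effect is
exp(β₁); the other subgroup's is exp(β₁ + β_int) with CI from the coefficient
covariance, so the two log-effects differ by exactly β_int, and
p_interaction is the Wald test on β_int. No multiplicity correction is
applied across modifiers and outcomes; reports should say so. Null
calibration (p_interaction uniform under β_int = 0) and joint recovery of
distinct subgroup odds ratios are exercised in the acceptance suite.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any real geography:

- **Panel.** Lognormal marginals per constituent anchored to published US
  zip-code-level medians and IQRs (σ = ln(q75/q25)/1.349), coupled by a
  Gaussian copula with exchangeable correlation ρ = 0.5 plus a stronger
  secondary-aerosol block (NH₄⁺, NO₃, SO₄²⁻ at ρ = 0.8), two consecutive
  years per zip with latent year-to-year correlation 0.9. Non-positive-
  definite user correlation matrices are rejected with a nearest-PD hint.
- **Recipients.** Multinomial zip assignment with lognormal-skewed zip sizes
  (urban clustering); age ~ N(51.6, 13.5²), 39% female, 61% deceased-donor,
  cold ischemia time gamma-matched to mean 12.8 h / SD 10.8 h, and one
  standard-normal area-deprivation score — a minimal stand-in for the full
  recipient/donor/contextual covariate set. An optional confounding knob
  reorders deprivation toward high-exposure zips.
- **Outcomes.** Binary outcomes are Bernoulli draws from the logistic model
  on the true weighted decile index (baseline prevalence 0.186,
  delayed-graft-function-like; default per-decile OR 1.08, with the
  rejection outcome at half the log-effect). Survival outcomes are
  month-by-month Bernoulli draws from the logit hazard model (constant
  baseline 0.002/month ≈ 11% five-year cumulative incidence,
  mortality-like; default per-decile hazard OR 1.047), with independent
  monthly dropout 0.005 and administrative censoring at 60 months. True
  weights default to (0.5, 0.3, 0.2, 0 × 12).
- Every generating parameter is serialised in a truth record next to the
  data; identical config + seed reproduces byte-identical CSV/JSON bundles.

What passing tests on these cohorts do **not** show: robustness to exposure
measurement error, residential mobility, informative censoring, real
spatial structure, or confounding patterns beyond the simple knob above.

## Problem sizes and statistical power of the checks

Recovery simulations use effect sizes large enough to be informative at
desk scale. The per-weight sampling noise of the constrained MLE scales as
[n·p(1−p)·var(d)]^(−1/2)/β₁: at a per-decile OR of 1.08 (the scale of the
motivating application, whose cohorts run to ~2×10⁵ recipients) weight
identification requires cohort sizes far beyond quick tests, so recovery
checks use OR 1.2, where a training half of ~6 000+ recipients suffices to
rank the generating constituents correctly and separate signal from null
weights. End-to-end checks run at n = 16 000 recipients / 1 200 zips
(binary) and n = 4 000 (survival); calibration loops use 100–200 replicates.
These sizes were chosen for statistical adequacy of each check and are
stated in the tests and acceptance script.

## Numerical choices

- Optimiser tolerances: L-BFGS ftol 1e-8, SLSQP polish ftol 1e-12; weight
  simplex enforced to |Σw − 1| ≤ 1e-8 at every exit.
- Quantile ties: lower bin (right-closed intervals).
- Degenerate inputs: constant constituents score 0 with a warning; zero
  events, singular designs, non-binary modifiers and invalid fractions are
  errors, not silent results.
- Statsmodels fit objects drop their design arrays after the needed
  coefficients and covariances are extracted, keeping long replicate loops
  at constant memory.
- Run manifests record the config snapshot, seed fan-out, package version
  and SHA-256 input digests; wall-clock timings are written to a separate
  run log so manifests are reproducible byte for byte.
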