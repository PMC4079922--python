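# Methods

This note documents the statistical models implemented in `vitd_uacr`, the
assumptions behind them, the design decisions taken where the procedure was
genuinely open, and what the synthetic-data experiments do and do not show.

## The scientific problem

In adults without overt albuminuria (urinary albumin-creatinine ratio,
UACR < 30 mg/g), the question is whether urinary albumin excretion starts to
rise only once serum 25-hydroxyvitamin D (25(OH)D) falls below some
threshold τ, rather than varying with vitamin D status across its whole
range. The package implements the full analysis chain for that question:
harmonizing 25(OH)D measurements across laboratories, restricting to the
normoalbuminuric analysis population, locating τ by comparing change-point
models on an AIC grid, and quantifying the risk of *high-normal* urinary
albumin excretion (UACR 10–29 mg/g) across vitamin D categories by logistic
regression.

## Synthetic cohort generator

No subject-level data are distributed, so the analysis is exercised on
synthetic cohorts whose marginal structure matches the baseline table of a
large Korean health-screening population (n = 14,594).

**Generative model.** Serum 25(OH)D is conditionally normal given
covariates, truncated at 0 ng/mL *by resampling the noise* (clipping would
put an atom at 0). Log-UACR follows a hockey-stick link:

    log UACR = μ₀ + β · max(0, τ* − D) + Σ covariate terms + ε,
    ε ~ N(0, σ²)

i.e. flat in 25(OH)D = D above the change point τ* and rising linearly as D
falls below it. UACR is therefore log-normal given covariates, reproducing
the strong right skew of real UACR (median 4.3, IQR ≈ 2.5–7.7 mg/g) while
25(OH)D is approximately normal (mean 20.4, SD 8.4 ng/mL).

**Key defaults and why.**

| parameter | default | units | rationale |
|---|---|---|---|
| `vitd_mean`, `vitd_sd` | 20.4, 8.4 | ng/mL | published marginal moments |
| `log_uacr_mean` | ln 4.3 | log(mg/g) | target median; published value |
| `log_uacr_sd` | 0.72 | log(mg/g) | residual SD; with covariate and hinge variance the marginal spread matches the published IQR scale |
| `true_threshold` τ* | 8.0 | ng/mL | the multivariate-adjusted threshold the analysis is designed to recover |
| `below_threshold_slope` β | 0.3 | Δlog-UACR per ng/mL | free parameter (no effect size is reported for the real cohort); see below |
| prevalences | male 0.647, diabetes 0.092, hypertension 0.118, RAS blocker 0.069, supplement 0.069 | — | published Table margins |

**The slope is a simulation design choice, not an empirical claim.** The
source study reports no 25(OH)D–UACR effect size on any scale. β = 0.3 was
fixed once, at design time, by a Fisher-information calculation for the
profile change-point estimator in the hinge model: the information for τ per
observation is (β²/σ²)·Var(resid of 1{D<τ} on the other regressors); with
the default 25(OH)D distribution this residual variance is ≈ 0.020, giving
SE(τ̂) ≈ σ/(β√(0.020·n)) ≈ 0.14 ng/mL at n = 15,000 — small enough for a
0.2 ng/mL grid to resolve the change point reliably. A slope of 0.3
corresponds to UACR rising ≈ 35 %/ng/mL of 25(OH)D decline below τ*, a steep
but clearly identifiable hockey stick.

**Covariate structure.** Covariates are generated with modest, documented
effects on both variables (male sex and summer raise 25(OH)D; older age,
diabetes, hypertension and BMI raise UACR; winter lowers 25(OH)D), centered
so they do not move marginal locations. Because covariates shift *both*
variables, the marginal D–UACR association under β = 0 is slightly nonzero
(confounding by design, so adjustment machinery is exercised); flatness of
the link is a statement about the covariate-adjusted slope, and the tests
check it that way.

**Marginal calibration.** The exact location/scale of 25(OH)D (after
truncation) and the log-UACR baseline (after covariate and hinge shifts) are
solved by a fixed-point iteration on an internal fixed-seed Monte-Carlo
sample of 200,000 draws (4 iterations), cached per configuration. The
calibration is a deterministic function of the configuration and is
independent of the user-facing cohort seed.

**The exclusion fixture.** `generate_exclusion_fixture` builds a
16,870-record cohort in which the exclusion and reporting arithmetic holds
*by construction* for any seed: exactly 2,276 records with UACR ≥ 30 mg/g,
exactly 3 with 25(OH)D > 125 ng/mL nested inside that set (the published
totals only reconcile if the union has size 2,276), all ages ≥ 20, and —
among the 14,594 survivors — exactly 9,441 male and 4,089 with
25(OH)D < 15 ng/mL. Value distributions are plausible (the deficient /
non-deficient 25(OH)D groups use the published group moments 11.7 ± 2.3 and
23.8 ± 7.4 ng/mL) but the fixture pins counting margins only; it does not
carry the generator's dose-response link.

**What the generator does not emulate.** Inter-subject correlation beyond
the documented pairwise effects; longitudinal structure (single visit);
assay-specific measurement chemistry; missing data. Passing tests therefore
demonstrate correctness of the *procedures* under a known generative model,
not reproduction of estimates from the unreleased hospital data.

## Multi-site harmonization

Quantile normalization forces per-site distributions to coincide by
averaging values at equal rank. For clinical interpretability the
stratified variant partitions each site's values by the analyte's reference
range (below / within / above, with `lower ≤ x ≤ upper` counted as within)
and normalizes each stratum independently, so no measurement changes its
clinical category. Decisions where the procedure is under-determined:

- **Unequal site sizes** — each site's empirical quantile function is
  linearly interpolated onto a common probability grid, averaged, and each
  value mapped through the averaged quantile function at its average-rank
  plotting position. For equal sizes without ties this reduces exactly to
  classical rank averaging.
- **Ties** — tied values receive the mean of the rank-averages their ranks
  span (deterministic, order-preserving in the weak sense). With ties the
  "identical multiset" property holds only approximately.
- **Boundary crossing** — if averaging would push a value across its
  stratum boundary it is clamped just inside the stratum and the clamp is
  logged.
- **Empty strata** — a stratum empty at one site but populated at another
  has no cross-site ranks to average; those values pass through unchanged
  with a warning.

## Cohort preparation

Exclusions retain records with complete required fields, age ≥ 20 years,
25(OH)D ≤ 125 ng/mL and UACR < 30 mg/g; the log reports per-reason counts
and the overlap-aware union. Derivations: eGFR by the four-variable MDRD
equation 175·Scr⁻¹·¹⁵⁴·age⁻⁰·²⁰³·(0.742 if female), race term omitted for a
single-ethnicity cohort; season by calendar quarter (spring = March–May,
etc.).

Vitamin D categories: cohort quartiles (Q4 reference); fixed percentiles
with cuts at the 5th/25th/50th cohort percentiles (top half reference); and
clinical cut-offs. Two conventions close gaps left open by the usual
printed definitions: *sufficiency* is implemented as ≥ 30.0 ng/mL (the
printed "insufficiency 15.0–29.9 / sufficiency > 30" leaves (29.9, 30)
undefined; a half-open partition has no gap), and the lowest percentile bin
is [0, 5th percentile) (the printed "1.0–4.9th" leaves the bottom 1 %
unassigned; the partition must be exhaustive). Quantiles use the
linear-interpolation (type-7) convention and boundary values go to the
upper bin. UACR and hs-CRP (and triglyceride) are treated as skewed in
descriptive tables — median (IQR), Mann-Whitney U — everything else as
mean ± SD with a t-test, binaries as N/% with chi-squared.

## Threshold detection

**Model family.** The default change-point model is a one-knot linear
spline, `response ~ covariates + α·D + δ·(τ − D)₊`, fitted by least squares
for each candidate τ on a 0.2 ng/mL grid. Every candidate has the same
model dimension, so the Gaussian AIC, `n·log(RSS/n) + 2(edf + 1)` (constant
terms dropped; the same convention across candidates leaves the arg-min
invariant), compares them on equal footing. "UACR begins to rise below τ"
is the single parameter δ. A variant (`smooth=True`) replaces α·D with a
penalized smooth of D, refitted per candidate with AIC computed from the
effective degrees of freedom.

**Penalized smoother.** The partially linear additive model uses a cubic
B-spline basis (default dimension 10) on quantile-spaced interior knots
with a second-order *divided-difference* penalty over the Greville
abscissae. The divided-difference form (rather than plain index
differences) makes the penalty null space exactly the functions linear in
D for any knot layout, so the λ → ∞ limit is exactly the multiple linear
regression of y on [covariates, D]. λ is chosen by GCV, n·RSS/(n − edf)²,
on 40 log-spaced points in [1e-4, 1e8] with ties toward the smoother fit;
edf is the trace of the influence matrix; identifiability against the
intercept is handled by reparameterizing the spline block onto the
orthogonal complement of the constant function. Curve bands use the
Bayesian posterior covariance σ²(MᵀM + λP)⁻¹ of the penalized fit.

**Scan conventions.** Grid default [4.0, 30.0] ng/mL, clipped to the
1st–99th percentile of observed 25(OH)D; ties in AIC break toward smaller
τ; a boundary selection raises a warning. A no-threshold null model
(covariates + linear D) is always fitted and a threshold is reported only
when the best candidate beats it on AIC; the margin is reported. Under a
flat link the AIC profile is flat to within a few units and the null
typically wins; the margin is small either way, and no formal selection
test is attempted beyond the AIC comparison.

**Response scale.** The scan accepts raw UACR (the Gaussian-model
convention of the original analysis) or log-UACR. Simulation studies and
the acceptance script use log-UACR: it is the generative scale, and the
heavy right tail of raw UACR makes Gaussian least squares inefficient.

**Adjustment sets.** `none`; `demo` (age, sex, season); `full` (age, sex,
season, BMI, hemoglobin, eGFR, hypertension, diabetes, vitamin D
supplement, RAS blocker, serum albumin, calcium, phosphorus,
HDL-cholesterol, triglyceride, hs-CRP). Sex enters as a male indicator,
season as three indicators (spring reference).

## Association models

Logistic regression is fitted by IRLS (Newton-Raphson), converging when the
largest coefficient change is below 1e-8 (max 100 iterations); degenerate
outcomes and (quasi-)separation raise diagnostic errors. Confidence
intervals are Wald on the log-odds scale with the fixed 1.96 multiplier.
Category odds ratios contrast each level against the highest (reference)
category; categories with zero events are flagged and omitted. In
diabetes-stratified models the diabetes indicator is dropped from the
adjustment set (it is constant within a stratum); category cut points
always come from the whole cohort.

Lowess is locally weighted linear regression with tricube weights over the
span-nearest neighbors (defaults: span 2/3, 3 bisquare robustness
iterations — conventional values). The predicted-probability curve fits
the multivariate logistic model with 25(OH)D entering through a small
unpenalized B-spline (6 basis functions, sum-to-zero constrained) so the
fitted risk shape is data-driven, takes each subject's predicted
probability at their observed covariates (population-averaged, matching a
"predicted prevalence" reading), and smooths the probabilities against
25(OH)D on a 100-point grid. The pointwise 95 % band is curve ± 1.96 ×
bootstrap SE over 200 seeded resamples of subjects (a normal-approximation
band, which by construction contains the point estimate); resamples that
quasi-separate the tail spline terms are redrawn.

## Numerical choices and degenerate inputs

- Quantile normalization: empty panels are errors; a single panel is a
  warned no-op.
- Spline basis: constant x is an error; dimension ≥ 4 required; interior
  knots are clipped inside the data range to keep the basis full-rank.
- IRLS separation heuristic: linear predictors beyond ±30 with fitted
  probabilities numerically 0/1.
- Lowess: fewer than 10 points, span outside (0, 1], or windows of fewer
  than 3 points are errors; robustness iterations stop when residuals are
  at numerical zero.
- Mann-Whitney U uses the exact null distribution for groups ≤ 25, the
  normal approximation otherwise.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use cohorts of 2,000–50,000 subjects. The
change-point recovery experiment uses 20 cohorts of n = 15,000 (the scale
of the real analysis population) and requires the 0.2-grid scan with full
adjustment to land within two grid steps of τ* = 8.0 ng/mL in at least
18 of 20 seeds, with the modal selection equal to τ*. Generator
calibration is checked at n = 14,594 against median UACR 4.3 mg/g (within
two bootstrap SEs, 500 resamples) and mean 25(OH)D 20.4 ng/mL (within two
SEs).

## Known limitations

- The change-point model family (linear spline vs. refitted smooth) is a
  package decision; the original analysis specifies only the AIC-grid
  contract, not the per-candidate model form.
- Odds-ratio magnitudes from synthetic cohorts depend on the free slope β
  and are not comparable to estimates from the unreleased hospital data.
- Stratified quantile normalization assumes a common reference range per
  analyte across sites and does not convert between assay platforms.
- Complete-case analysis only; no imputation of missing covariates.
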