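# vitd-uacr

Threshold analysis of serum 25-hydroxyvitamin D (25(OH)D) and the urinary
albumin-creatinine ratio (UACR) in normoalbuminuric adults.

Low-grade ("high-normal") urinary albumin excretion — UACR 10–29 mg/g,
below the conventional microalbuminuria cut-off — predicts cardiovascular
disease and mortality in the general population, and severe vitamin D
deficiency is a candidate modifiable risk factor for it. The scientific
question this package addresses is *non-linearity*: whether mean UACR is
flat across most of the 25(OH)D range and begins to rise only below a
threshold τ, and how to estimate τ from multi-site screening data.

The package is aimed at biostatisticians and epidemiologists who want the
full analysis chain as tested, reusable components:

- **`synthetic_cohort`** — a calibrated cohort generator (no subject-level
  data are distributed). 25(OH)D ~ N(20.4, 8.4²) ng/mL truncated at 0;
  UACR log-normal (median 4.3 mg/g) with a hockey-stick link
  `E[log UACR | D] = μ₀ + β·max(0, τ* − D)` plus covariate structure; a
  deterministic 16,870-record fixture reproduces the study-style exclusion
  arithmetic exactly.
- **`lab_harmonization`** — reference-range-stratified quantile
  normalization: per-site values are partitioned into below/within/above
  the reference range and values of equal rank are averaged across sites
  within each stratum, so distributions are aligned without changing any
  measurement's clinical category.
- **`cohort_prep`** — inclusion/exclusion rules (age ≥ 20,
  25(OH)D ≤ 125 ng/mL, UACR < 30 mg/g), MDRD eGFR, season mapping, UAE and
  vitamin D categorization (quartile / percentile / clinical schemes), and
  two-group descriptive tables with t, Mann-Whitney U and chi-squared
  tests.
- **`gam_threshold`** — the core estimator. For each candidate τ on a
  0.2 ng/mL grid, the Gaussian change-point model
  `y ~ covariates + α·D + δ·(τ − D)₊` is fitted and scored by
  `AIC = n·log(RSS/n) + 2(edf + 1)`; the selected threshold is the AIC
  arg-min, reported only when it beats the no-threshold null
  (`covariates + α·D`). A partially linear penalized B-spline smoother
  (second-order divided-difference penalty, GCV-selected λ) provides the
  smooth-curve view and a per-candidate smooth variant.
- **`association`** — logistic regression (IRLS) of high-normal UAE on
  vitamin D categories with Wald CIs, highest category as reference,
  optional diabetes stratification; lowess; predicted-probability curves
  with bootstrap bands.
- **`pipeline` / CLI** — `vitd-uacr simulate|normalize|prepare|scan|associate|run`
  ties the stages together with CSV/JSON interchange and a reproducibility
  manifest.

## Worked example

```python
import numpy as np
from vitd_uacr import (GeneratorConfig, generate_cohort, apply_exclusions,
                       threshold_scan, category_or)

cfg = GeneratorConfig(n_subjects=15_000, seed=1)   # true threshold 8.0 ng/mL
cohort = generate_cohort(cfg)
retained, log = apply_exclusions(cohort)
print(f"recruited {log.n_input}, excluded {log.n_excluded_union} "
      f"(UACR>=30: {log.n_excluded_uacr}), analyzed {log.n_retained}")

scan = threshold_scan(retained, adjust="full", grid_low=4.0, grid_high=20.0,
                      step=0.2, log_uacr=True)
print(f"selected threshold: {scan.selected_tau:.1f} ng/mL "
      f"(AIC margin over no-threshold model: {scan.aic_margin:.1f})")

for r in category_or(retained, "clinical", adjust="full"):
    ci = "" if r.ci_low is None else f" (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})"
    print(f"  {r.level:>13}: OR {r.oratio:.2f}{ci}   n={r.n}, events={r.n_events}")
```

Output:

```
recruited 15000, excluded 216 (UACR>=30: 216), analyzed 14784
selected threshold: 8.2 ng/mL (AIC margin over no-threshold model: 828.9)
     deficiency: OR 1.59 (95% CI 1.34-1.88)   n=3899, events=708
  insufficiency: OR 0.91 (95% CI 0.78-1.07)   n=9014, events=1011
    sufficiency: OR 1.00   n=1871, events=222
```

Reading it: of 15,000 simulated screening subjects, 216 with UACR ≥ 30 mg/g
are excluded, leaving a normoalbuminuric analysis population. The AIC grid
scan with full multivariate adjustment localizes the change point at
8.2 ng/mL — one grid step from the generator's true τ* = 8.0 — and the AIC
margin (≈ 829 units better than the straight-line model) is overwhelming
evidence of non-linearity. In the clinical categorization, only the
deficiency group (< 15 ng/mL) shows elevated odds of high-normal UAE
(OR 1.59) relative to sufficiency, because under a τ* = 8 hockey stick the
risk is carried entirely by the far-left tail; insufficiency is
indistinguishable from the reference.

The same run end-to-end, from the shell:

```bash
vitd-uacr run --seed 1 --outdir out/          # writes cohort.csv, retained.csv,
                                              # table1.tsv, scan_table.csv,
                                              # threshold.json, or_table.csv,
                                              # curve.csv, figures, manifest.json
```

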