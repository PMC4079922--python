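"""Cohort preparation: inclusion/exclusion rules, derived variables, categories.

The analysis population is restricted to normoalbuminuric adults: age >= 20
years, serum 25-hydroxyvitamin D (25(OH)D) <= 125 ng/mL, and urinary
albumin-creatinine ratio (UACR) < 30 mg/g.  Within that population, urinary
albumin excretion (UAE) status is dichotomized as *normal* (UACR < 10 mg/g)
versus *high-normal* (UACR 10-29 mg/g), and vitamin D status is categorized
under three schemes (cohort quartiles, fixed cohort percentiles, clinical
cut-offs).  This module also derives eGFR (four-variable MDRD), maps
examination month to season, and builds two-group descriptive tables with the
conventional tests (t, Mann-Whitney U, chi-squared).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_FIELDS",
    "SKEWED_VARIABLES",
    "ExclusionLog",
    "VitDCategory",
    "apply_exclusions",
    "assign_season",
    "classify_uae",
    "classify_vitd",
    "compute_egfr",
    "descriptive_table",
    "vitd_scheme_info",
]

#: Fields every record must carry to pass the exclusion filter.
REQUIRED_FIELDS = ("age", "serum_25ohd", "uacr")

#: Variables summarized as median (IQR) and compared by Mann-Whitney U.
SKEWED_VARIABLES = frozenset({"uacr", "hs_crp", "triglyceride"})

# Exclusion cut-offs for the analysis population.
AGE_MIN = 20.0
VITD_OUTLIER = 125.0   # ng/mL; strictly greater is excluded
UACR_EXCLUDE = 30.0    # mg/g; >= 30 (microalbuminuria and above) is excluded

UAE_HIGH_NORMAL_LOW = 10.0   # mg/g

# Clinical 25(OH)D cut points: deficiency < 15, insufficiency [15, 30),
# sufficiency >= 30 ng/mL (half-open partition, no gap).
CLINICAL_DEFICIENCY = 15.0
CLINICAL_SUFFICIENCY = 30.0

_SEASONS = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}

SEASON_LEVELS = ("spring", "summer", "autumn", "winter")


# ---------------------------------------------------------------------------
# Derived variables
# ---------------------------------------------------------------------------

def compute_egfr(serum_creatinine, age, sex):
    """Estimated GFR by the four-variable MDRD equation, mL/min/1.73 m^2.

    eGFR = 175 * Scr^-1.154 * age^-0.203 * (0.742 if female).  The race term
    is omitted (single-ethnicity cohort).  Inputs may be scalars or arrays;
    ``sex`` holds ``"male"``/``"female"`` labels.

    Raises
    ------
    ValueError
        If any creatinine or age value is non-positive.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age_a = np.asarray(age, dtype=float)
    sex_a = np.asarray(sex)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age_a <= 0):
        raise ValueError("age must be positive")
    egfr = 175.0 * scr ** -1.154 * age_a ** -0.203
    egfr = egfr * np.where(sex_a == "female", 0.742, 1.0)
    if np.isscalar(serum_creatinine) and np.isscalar(age):
        return float(egfr)
    return egfr


def assign_season(exam_month):
    """Map examination month (1-12) to season.

    Spring is March-May, summer June-August, autumn September-November,
    winter December-February.
    """
    months = np.atleast_1d(np.asarray(exam_month))
    if not np.all(np.isin(months, list(range(1, 13)))):
        bad = sorted(set(months[~np.isin(months, list(range(1, 13)))].tolist()))
        raise ValueError(f"exam_month outside 1-12: {bad}")
    mapped = np.array([_SEASONS[int(m)] for m in months])
    if np.isscalar(exam_month):
        return str(mapped[0])
    return mapped


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

@dataclass
class ExclusionLog:
    """Overlap-aware accounting of the exclusion filter."""

    n_input: int = 0
    n_excluded_missing: int = 0
    n_excluded_age: int = 0
    n_excluded_vitd_outlier: int = 0
    n_excluded_uacr: int = 0
    n_excluded_union: int = 0
    n_retained: int = 0
    #: record index -> sorted list of reason codes, for excluded records only
    reasons: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["reasons"] = {str(k): v for k, v in self.reasons.items()}
        return json.dumps(d, indent=2)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the study inclusion/exclusion rules.

    Retains records with complete required fields, age >= 20 years,
    serum 25(OH)D <= 125 ng/mL, and UACR < 30 mg/g.  Records failing more
    than one rule are excluded once; the log reports both per-reason counts
    and the union count (``n_excluded_union`` includes missing-field
    rejections, which are also counted separately).
    """
    log = ExclusionLog(n_input=len(cohort))
    if len(cohort) == 0:
        return cohort.copy(), log

    missing = pd.Series(False, index=cohort.index)
    for col in REQUIRED_FIELDS:
        if col in cohort.columns:
            missing |= cohort[col].isna()
        else:
            missing |= True

    def _col(name):
        return pd.to_numeric(cohort.get(name, np.nan), errors="coerce")

    age = _col("age")
    vitd = _col("serum_25ohd")
    uacr = _col("uacr")

    young = (~missing) & (age < AGE_MIN)
    vitd_out = (~missing) & (vitd > VITD_OUTLIER)
    uacr_high = (~missing) & (uacr >= UACR_EXCLUDE)

    excluded = missing | young | vitd_out | uacr_high
    for idx in cohort.index[excluded]:
        codes = []
        if missing.loc[idx]:
            codes.append("missing")
        if young.loc[idx]:
            codes.append("age_lt_20")
        if vitd_out.loc[idx]:
            codes.append("vitd_outlier")
        if uacr_high.loc[idx]:
            codes.append("uacr_ge_30")
        log.reasons[idx] = codes

    log.n_excluded_missing = int(missing.sum())
    log.n_excluded_age = int(young.sum())
    log.n_excluded_vitd_outlier = int(vitd_out.sum())
    log.n_excluded_uacr = int(uacr_high.sum())
    log.n_excluded_union = int(excluded.sum())
    log.n_retained = int((~excluded).sum())
    return cohort.loc[~excluded].copy(), log


# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------

def classify_uae(uacr):
    """Classify urinary albumin excretion: ``normal`` (< 10 mg/g) vs
    ``high_normal`` (10-29 mg/g).

    Values >= 30 mg/g or negative are a domain error: they must have been
    excluded upstream (normoalbuminuric analysis population).
    """
    vals = np.atleast_1d(np.asarray(uacr, dtype=float))
    if np.any(np.isnan(vals)) or np.any(vals < 0) or np.any(vals >= UACR_EXCLUDE):
        raise ValueError(
            "UACR out of the normoalbuminuric domain [0, 30); "
            "run apply_exclusions first"
        )
    labels = np.where(vals < UAE_HIGH_NORMAL_LOW, "normal", "high_normal")
    if np.isscalar(uacr):
        return str(labels[0])
    return labels


@dataclass(frozen=True)
class VitDCategory:
    """One level of a vitamin D categorization scheme."""

    scheme: str
    label: str
    lower: float            # ng/mL, inclusive (-inf for the lowest level)
    upper: float            # ng/mL, exclusive (+inf for the highest level)
    reference: bool = False # the highest level is the comparison reference


_SCHEMES = ("quartile", "percentile", "clinical")
_PERCENTILE_PROBS = (0.05, 0.25, 0.50)


def _scheme_cuts(scheme: str, cohort_values) -> tuple[np.ndarray, list[str]]:
    if scheme == "quartile":
        cuts = np.quantile(np.asarray(cohort_values, dtype=float), [0.25, 0.5, 0.75])
        labels = ["Q1", "Q2", "Q3", "Q4"]
    elif scheme == "percentile":
        cuts = np.quantile(np.asarray(cohort_values, dtype=float), _PERCENTILE_PROBS)
        labels = ["<5.0th", "5.0-24.9th", "25.0-49.9th", "50.0-100.0th"]
    elif scheme == "clinical":
        cuts = np.array([CLINICAL_DEFICIENCY, CLINICAL_SUFFICIENCY])
        labels = ["deficiency", "insufficiency", "sufficiency"]
    else:
        raise ValueError(f"unknown vitamin D scheme {scheme!r}")
    return cuts, labels


def vitd_scheme_info(scheme: str, cohort_values=None) -> list[VitDCategory]:
    """Describe the levels of a categorization scheme as interval objects.

    ``cohort_values`` supplies the retained cohort's 25(OH)D values for the
    data-driven (quartile/percentile) schemes; quantiles use the linear
    interpolation convention, and values exactly at a cut point fall into the
    upper bin.
    """
    if scheme in ("quartile", "percentile") and cohort_values is None:
        raise ValueError(f"{scheme} scheme requires cohort values")
    cuts, labels = _scheme_cuts(scheme, cohort_values)
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    return [
        VitDCategory(scheme, lab, float(lo), float(hi), reference=(i == len(labels) - 1))
        for i, (lab, lo, hi) in enumerate(zip(labels, edges[:-1], edges[1:]))
    ]


def classify_vitd(serum_25ohd, scheme: str, cohort_values=None):
    """Assign each 25(OH)D value (ng/mL) to its category under ``scheme``.

    Schemes: ``quartile`` (cohort Q1/Q2/Q3 cut points, Q4 = reference),
    ``percentile`` (5th/25th/50th cohort percentiles, top half = reference),
    ``clinical`` (deficiency < 15.0, insufficiency 15.0-29.9,
    sufficiency >= 30.0 ng/mL = reference).  Returns an ordered pandas
    Categorical (scalar input returns the label string).
    """
    if scheme in ("quartile", "percentile") and cohort_values is None:
        cohort_values = serum_25ohd
    cuts, labels = _scheme_cuts(scheme, cohort_values)
    vals = np.atleast_1d(np.asarray(serum_25ohd, dtype=float))
    # boundary values go to the upper bin
    idx = np.searchsorted(cuts, vals, side="right")
    cats = pd.Categorical.from_codes(idx, categories=labels, ordered=True)
    if np.isscalar(serum_25ohd):
        return str(cats[0])
    return cats


# ---------------------------------------------------------------------------
# Descriptive comparisons
# ---------------------------------------------------------------------------

def _is_binary(series: pd.Series) -> bool:
    if series.dtype == bool:
        return True
    vals = pd.unique(series.dropna())
    return len(vals) <= 2 and set(np.asarray(vals).tolist()) <= {0, 1, True, False}


def descriptive_table(
    cohort: pd.DataFrame,
    group_col: str,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group descriptive comparison in the style of a baseline table.

    Normal-ish continuous variables are shown as mean +/- SD and compared by
    Student's t-test; right-skewed variables (UACR, hs-CRP, triglyceride) as
    median (IQR) with the Mann-Whitney U test; binary variables as N/% with
    the chi-squared test; multi-level categoricals (season) as per-level N/%
    with a contingency chi-squared.  P-values are two-sided.  A group with
    fewer than 2 observations gets its summary but the test is suppressed
    (``test_suppressed`` flag).
    """
    groups = [g for g in pd.unique(cohort[group_col].dropna())]
    if len(groups) != 2:
        raise ValueError(f"grouping column {group_col!r} must have exactly 2 levels, got {groups}")
    g0, g1 = groups
    a = cohort[cohort[group_col] == g0]
    b = cohort[cohort[group_col] == g1]
    suppress = len(a) < 2 or len(b) < 2

    if variables is None:
        variables = [
            c for c in cohort.columns
            if c not in (group_col, "subject_id", "site_id", "exam_month")
        ]

    rows = []
    for var in variables:
        sa = a[var].dropna()
        sb = b[var].dropna()
        entry = {"variable": var, "group_a": str(g0), "group_b": str(g1),
                 "n_a": len(sa), "n_b": len(sb), "test_suppressed": suppress}
        if _is_binary(cohort[var]):
            ca, cb = int(np.sum(sa.astype(bool))), int(np.sum(sb.astype(bool)))
            entry["summary_a"] = f"{ca}/{100 * ca / max(len(sa), 1):.1f}%"
            entry["summary_b"] = f"{cb}/{100 * cb / max(len(sb), 1):.1f}%"
            entry["test"] = "chi2"
            if not suppress:
                tbl = np.array([[ca, len(sa) - ca], [cb, len(sb) - cb]])
                if tbl.sum(axis=0).min() == 0:
                    entry["p"] = np.nan
                else:
                    entry["p"] = float(stats.chi2_contingency(tbl, correction=False)[1])
        elif cohort[var].dtype == object or isinstance(cohort[var].dtype, pd.CategoricalDtype):
            counts = pd.crosstab(cohort[group_col], cohort[var])
            entry["summary_a"] = "; ".join(
                f"{lv}: {counts.loc[g0, lv]}/{100 * counts.loc[g0, lv] / max(len(sa), 1):.1f}%"
                for lv in counts.columns)
            entry["summary_b"] = "; ".join(
                f"{lv}: {counts.loc[g1, lv]}/{100 * counts.loc[g1, lv] / max(len(sb), 1):.1f}%"
                for lv in counts.columns)
            entry["test"] = "chi2"
            if not suppress:
                entry["p"] = float(stats.chi2_contingency(counts.values, correction=False)[1])
        elif var in SKEWED_VARIABLES:
            qa = np.percentile(sa, [25, 50, 75])
            qb = np.percentile(sb, [25, 50, 75])
            entry["summary_a"] = f"{qa[1]:.2f} ({qa[0]:.2f}-{qa[2]:.2f})"
            entry["summary_b"] = f"{qb[1]:.2f} ({qb[0]:.2f}-{qb[2]:.2f})"
            entry["test"] = "mannwhitney"
            if not suppress:
                method = "exact" if max(len(sa), len(sb)) <= 25 else "asymptotic"
                entry["p"] = float(stats.mannwhitneyu(
                    sa, sb, alternative="two-sided", method=method).pvalue)
        else:
            entry["summary_a"] = f"{sa.mean():.2f} +/- {sa.std(ddof=1):.2f}"
            entry["summary_b"] = f"{sb.mean():.2f} +/- {sb.std(ddof=1):.2f}"
            entry["test"] = "ttest"
            if not suppress:
                if sa.std(ddof=1) == 0 and sb.std(ddof=1) == 0 and sa.mean() == sb.mean():
                    entry["t"], entry["p"] = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(sa, sb)
                    entry["t"], entry["p"] = float(t), float(p)
        rows.append(entry)
    return pd.DataFrame(rows)
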