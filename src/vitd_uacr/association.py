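"""Logistic-regression association of vitamin D status with high-normal UAE.

High-normal urinary albumin excretion (UACR 10-29 mg/g) is modeled as a
binary outcome.  Odds ratios are estimated per vitamin D categorization
scheme with indicator contrasts against the highest (reference) category,
optionally adjusted for the standard multivariate covariate set and
optionally stratified by diabetes (the diabetes indicator is dropped from
the adjustment set within strata, where it is constant).

The logistic fitter is iteratively reweighted least squares (equivalently
Newton-Raphson on the log-likelihood), converging when the largest
coefficient change falls below 1e-8; Wald covariance comes from the final
weighted information matrix and confidence intervals are
exp(b +/- 1.96 se) on the log-odds scale.

A lowess smoother (locally weighted linear regression with tricube weights
over the span-nearest neighbors, optional bisquare robustness reweighting)
supports the predicted-probability curve: per-subject predicted
probabilities from the multivariate model — with 25(OH)D entering through a
small unpenalized spline so the curve's shape is data-driven — are smoothed
against 25(OH)D, with a pointwise 95% band from a seeded bootstrap over
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_prep import classify_uae, classify_vitd
from .gam_threshold import build_design, build_spline_basis

__all__ = [
    "LogisticFit",
    "ORResult",
    "ProbabilityCurve",
    "SeparationError",
    "category_or",
    "fit_logistic",
    "lowess",
    "predicted_probability_curve",
]


class SeparationError(RuntimeError):
    """Raised when the outcome is (quasi-)separable or degenerate."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray              # Wald covariance, inverse observed information
    names: list[str]
    n: int
    deviance: float
    n_iter: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, X) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.coef)


def fit_logistic(y, X, names: list[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Raises :class:`SeparationError` for a degenerate outcome (no events or
    all events) or complete separation (fitted probabilities escaping to
    0/1), and ``RuntimeError`` (reporting the last deviance) if IRLS does
    not converge within ``max_iter`` iterations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.sum() == 0 or y.sum() == n:
        raise SeparationError("degenerate outcome: all responses identical")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    deviance = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        if np.max(np.abs(eta)) > 30.0:
            mu_ = expit(eta)
            frac_extreme = np.mean((mu_ < 1e-10) | (mu_ > 1 - 1e-10))
            if frac_extreme > 0:
                raise SeparationError(
                    f"complete or quasi-complete separation suspected: "
                    f"{100 * frac_extreme:.1f}% of fitted probabilities are "
                    f"numerically 0/1 at iteration {it}")
        mu = expit(eta)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        mu = expit(X @ beta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        deviance = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if step < tol:
            w = mu * (1.0 - mu)
            info = X.T @ (X * w[:, None])
            return LogisticFit(coef=beta, cov=np.linalg.inv(info),
                               names=names or [f"x{j}" for j in range(p)],
                               n=n, deviance=deviance, n_iter=it)
    raise RuntimeError(f"IRLS did not converge in {max_iter} iterations "
                       f"(last deviance {deviance:.6g})")


# ---------------------------------------------------------------------------
# Categorical odds ratios
# ---------------------------------------------------------------------------

@dataclass
class ORResult:
    """Odds ratio for one vitamin D category against the reference level."""

    scheme: str
    level: str
    reference_level: str
    oratio: float | None          # None when omitted (zero-event cell)
    ci_low: float | None
    ci_high: float | None
    adjustment: str
    stratum: str                  # all | diabetes | no-diabetes
    n: int
    n_events: int
    is_reference: bool = False
    omitted: bool = False


def _one_stratum_or(df: pd.DataFrame, scheme: str, adjust: str, stratum: str,
                    cohort_values: np.ndarray) -> list[ORResult]:
    cats = classify_vitd(df["serum_25ohd"].to_numpy(float), scheme, cohort_values)
    levels = list(cats.categories)
    ref = levels[-1]
    y = (np.asarray(classify_uae(df["uacr"].to_numpy(float))) == "high_normal").astype(float)

    adj_cols = adjust
    if stratum != "all" and adjust != "none":
        from .gam_threshold import ADJUSTMENT_SETS
        adj_cols = [c for c in ADJUSTMENT_SETS[adjust] if c != "diabetes"]
    X_adj, adj_names = build_design(df, adj_cols if adjust != "none" else "none")

    results, keep_levels = [], []
    for lv in levels[:-1]:
        mask = np.asarray(cats == lv)
        n_ev = int(y[mask].sum())
        if n_ev == 0 or n_ev == int(mask.sum()):
            results.append(ORResult(scheme, lv, ref, None, None, None,
                                    adjust, stratum, int(mask.sum()), n_ev,
                                    omitted=True))
        else:
            keep_levels.append(lv)

    ind = np.column_stack([(np.asarray(cats == lv)).astype(float) for lv in keep_levels]) \
        if keep_levels else np.empty((len(df), 0))
    X = np.hstack([X_adj, ind])
    names = adj_names + [f"cat_{lv}" for lv in keep_levels]
    fit = fit_logistic(y, X, names=names)
    p0 = X_adj.shape[1]
    for j, lv in enumerate(keep_levels):
        b = fit.coef[p0 + j]
        se = fit.se()[p0 + j]
        mask = np.asarray(cats == lv)
        results.append(ORResult(scheme, lv, ref,
                                float(np.exp(b)),
                                float(np.exp(b - 1.96 * se)),
                                float(np.exp(b + 1.96 * se)),
                                adjust, stratum, int(mask.sum()),
                                int(y[mask].sum())))
    mask = np.asarray(cats == ref)
    results.append(ORResult(scheme, ref, ref, 1.0, None, None, adjust, stratum,
                            int(mask.sum()), int(y[mask].sum()), is_reference=True))
    order = {lv: i for i, lv in enumerate(levels)}
    results.sort(key=lambda r: order[r.level])
    return results


def category_or(cohort: pd.DataFrame, scheme: str, adjust: str = "full",
                stratify_by_diabetes: bool = False) -> list[ORResult]:
    """Odds ratios for high-normal UAE across vitamin D categories.

    One logistic model per scheme with indicator contrasts against the
    highest (reference) category.  ``adjust`` is ``"none"`` or ``"full"``
    (the standard multivariate list).  With ``stratify_by_diabetes`` separate
    models are fitted within the diabetes and no-diabetes strata; category
    cut points are always computed from the whole cohort.
    """
    cohort_values = cohort["serum_25ohd"].to_numpy(float)
    if not stratify_by_diabetes:
        return _one_stratum_or(cohort, scheme, adjust, "all", cohort_values)
    out = []
    for label, mask in [("no-diabetes", ~cohort["diabetes"].astype(bool)),
                        ("diabetes", cohort["diabetes"].astype(bool))]:
        out.extend(_one_stratum_or(cohort[mask], scheme, adjust, label, cohort_values))
    return out


def or_table(results: list[ORResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Lowess
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3


def _local_linear(x, y, w, x0):
    sw = w.sum()
    if sw <= 0:
        return np.nan
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 1e-12 * max(1.0, xm * xm):
        return ym
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    return ym + slope * (x0 - xm)


def lowess(x, y, frac: float = 2.0 / 3.0, it: int = 3, xvals=None) -> np.ndarray:
    """Locally weighted scatterplot smoothing.

    At each evaluation point, a linear fit is made by weighted least squares
    with tricube weights over the ``frac``-nearest neighbors; ``it``
    bisquare robustness iterations downweight outliers.  Returns smoothed
    values at the input ``x`` (in input order) or at ``xvals`` if given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("lowess needs at least 10 points")
    if not 0.0 < frac <= 1.0:
        raise ValueError("span fraction must lie in (0, 1]")
    k = int(np.ceil(frac * n))
    if k < 3:
        raise ValueError("span too small: fewer than 3 points in the local window")
    k = min(k, n)

    rob = np.ones(n)

    def _smooth_at(points):
        out = np.empty(len(points))
        for i, x0 in enumerate(points):
            dist = np.abs(x - x0)
            dk = np.partition(dist, k - 1)[k - 1]
            if dk == 0:
                w = (dist == 0).astype(float)
            else:
                w = _tricube(dist / dk)
            out[i] = _local_linear(x, y, w * rob, x0)
        return out

    for _ in range(it):
        fitted = _smooth_at(x)
        resid = y - fitted
        s = np.median(np.abs(resid))
        scale = np.mean(np.abs(y - y.mean()))
        if s <= 1e-9 * max(scale, 1e-300):   # residuals already at numerical zero
            break
        rob = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2

    return _smooth_at(x if xvals is None else np.asarray(xvals, dtype=float))


# ---------------------------------------------------------------------------
# Predicted-probability curve
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityCurve:
    """Lowess-smoothed predicted probability of high-normal UAE vs 25(OH)D."""

    grid: np.ndarray
    prob: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    adjustment: str
    n: int
    n_boot: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"serum_25ohd": self.grid, "prob": self.prob,
                             "lo": self.lo, "hi": self.hi})


def _prob_design(df: pd.DataFrame, adjust: str, spline_dim: int = 6,
                 include_vitd_spline: bool = True):
    X_adj, names = build_design(df, adjust)
    if not include_vitd_spline:
        return X_adj, names
    D = df["serum_25ohd"].to_numpy(float)
    B, _, _ = build_spline_basis(D, dimension=spline_dim)
    d = B.shape[1]
    ones = np.ones((d, 1)) / np.sqrt(d)
    Z = np.linalg.qr(np.eye(d) - ones @ ones.T)[0][:, : d - 1]
    X = np.hstack([X_adj, B @ Z])
    return X, names + [f"sD{j}" for j in range(d - 1)]


def predicted_probability_curve(
    cohort: pd.DataFrame,
    adjust: str = "full",
    frac: float = 2.0 / 3.0,
    n_boot: int = 200,
    seed: int = 0,
    grid_size: int = 100,
    include_vitd_spline: bool = True,
) -> ProbabilityCurve:
    """Population-averaged predicted-probability curve for high-normal UAE.

    Fits the multivariate logistic model (25(OH)D through a small unpenalized
    spline, covariates linear), takes each subject's predicted probability at
    their observed covariates, and smooths the probabilities against 25(OH)D
    by lowess on an evaluation grid spanning the 1st-99th percentile of
    25(OH)D.  The pointwise 95% band is curve +/- 1.96 times the bootstrap
    standard error over ``n_boot`` seeded resamples of subjects, clipped to
    (0, 1).
    """
    D = cohort["serum_25ohd"].to_numpy(float)
    y = (np.asarray(classify_uae(cohort["uacr"].to_numpy(float))) == "high_normal"
         ).astype(float)
    grid = np.linspace(*np.percentile(D, [1, 99]), grid_size)

    def _curve(df_b, y_b):
        X, _ = _prob_design(df_b, adjust, include_vitd_spline=include_vitd_spline)
        fit = fit_logistic(y_b, X)
        p_hat = fit.predict(X)
        return lowess(df_b["serum_25ohd"].to_numpy(float), p_hat,
                      frac=frac, it=0, xvals=grid)

    curve = _curve(cohort, y)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, grid_size))
    idx_all = np.arange(len(cohort))
    for b in range(n_boot):
        # a resample may thin the 25(OH)D tail enough to quasi-separate the
        # spline terms; redraw those (rare) resamples
        for _attempt in range(20):
            idx = rng.choice(idx_all, size=len(cohort), replace=True)
            try:
                boots[b] = _curve(cohort.iloc[idx], y[idx])
                break
            except SeparationError:
                continue
        else:
            raise SeparationError("bootstrap resamples repeatedly separated")
    se = boots.std(axis=0, ddof=1)
    eps = 1e-9
    return ProbabilityCurve(
        grid=grid,
        prob=np.clip(curve, eps, 1 - eps),
        lo=np.clip(curve - 1.96 * se, eps, 1 - eps),
        hi=np.clip(curve + 1.96 * se, eps, 1 - eps),
        adjustment=adjust, n=len(cohort), n_boot=n_boot, seed=seed)
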