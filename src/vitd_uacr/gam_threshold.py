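"""Penalized-spline smoothing of UACR on 25(OH)D and AIC-grid threshold search.

The core scientific question is whether mean UACR is flat in serum 25(OH)D
above some change point tau and rises as 25(OH)D falls below it, and at what
tau.  Two model families are provided:

* A partially linear penalized Gaussian additive model
  (:func:`fit_pgam`): y = X beta + f(D) + eps, with f represented in a cubic
  B-spline basis on quantile-spaced knots and a second-order
  divided-difference penalty over the Greville abscissae.  The penalty null
  space is exactly the functions linear in D, so as the smoothing parameter
  grows the fit converges to the multiple linear regression of y on [X, D].
  The smoothing parameter is chosen by generalized cross-validation (GCV) on
  a logarithmic grid; effective degrees of freedom are the trace of the
  influence (hat) matrix.

* A one-knot linear spline ("hockey stick"): y = X beta + alpha D +
  delta (tau - D)_+ + eps, fitted by least squares for each candidate tau on
  a grid of 0.2 ng/mL increments (:func:`threshold_scan`).  All candidates
  have the same model dimension, so Akaike's information criterion
  AIC = n log(RSS/n) + 2 (edf + 1) compares them on equal footing; the
  selected threshold is the AIC arg-min (ties toward smaller tau).  A
  no-threshold null model (covariates + linear D) is always fitted; a
  threshold is only reported when the best candidate beats the null on AIC,
  and the margin is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "ADJUSTMENT_SETS",
    "SmoothFit",
    "ThresholdScan",
    "build_design",
    "build_spline_basis",
    "fit_pgam",
    "plot_threshold_gam",
    "threshold_scan",
]

logger = logging.getLogger(__name__)

# Covariate adjustment sets.  "full" is the standard multivariate list:
# demographics, season, body habitus, hemoglobin, renal function,
# comorbidity and medication flags, and the biochemical panel.
ADJUSTMENT_SETS = {
    "none": [],
    "demo": ["age", "sex", "season"],
    "full": [
        "age", "sex", "season", "bmi", "hemoglobin", "egfr",
        "hypertension", "diabetes", "vitd_supplement", "ras_blocker",
        "serum_albumin", "serum_calcium", "serum_phosphorus",
        "hdl_cholesterol", "triglyceride", "hs_crp",
    ],
}

GCV_GRID = np.logspace(-4, 8, 40)   # lambda grid; ties resolved toward larger lambda


def build_design(cohort: pd.DataFrame, adjust: str | list[str]) -> tuple[np.ndarray, list[str]]:
    """Covariate design matrix (with intercept) for an adjustment set.

    ``sex`` enters as a male indicator and ``season`` as three indicators
    (spring reference); boolean flags as 0/1; everything else numeric.
    Collinear columns raise an error naming them.
    """
    names = ADJUSTMENT_SETS[adjust] if isinstance(adjust, str) else list(adjust)
    cols, labels = [np.ones(len(cohort))], ["intercept"]
    for name in names:
        if name == "sex":
            cols.append((cohort["sex"].to_numpy() == "male").astype(float))
            labels.append("male")
        elif name == "season":
            for s in ("summer", "autumn", "winter"):
                cols.append((cohort["season"].to_numpy() == s).astype(float))
                labels.append(f"season_{s}")
        else:
            cols.append(cohort[name].to_numpy(dtype=float))
            labels.append(name)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad, r = [], 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, :j + 1])
            if rj == r:
                bad.append(labels[j])
            r = rj
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    return X, labels


# ---------------------------------------------------------------------------
# Spline basis and penalty
# ---------------------------------------------------------------------------

def _greville(knots: np.ndarray, degree: int) -> np.ndarray:
    d = degree
    return np.array([knots[j + 1: j + 1 + d].mean() if d > 0 else knots[j]
                     for j in range(len(knots) - d - 1)])


def build_spline_basis(x, dimension: int = 10, degree: int = 3):
    """Cubic (by default) B-spline basis with quantile-spaced interior knots
    and a second-order divided-difference penalty.

    Returns ``(B, P, knots)``: the n-by-``dimension`` basis (rows sum to 1 on
    the data range), the ``dimension``-square penalty ``P = D' D`` where ``D``
    takes second divided differences of the coefficients over the Greville
    abscissae (so the penalty vanishes exactly on coefficient vectors linear
    in the Greville points, i.e. on functions linear in x), and the full knot
    vector.
    """
    x = np.asarray(x, dtype=float)
    if dimension < 4:
        raise ValueError("basis dimension must be >= 4")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; cannot build a spline basis")
    n_interior = dimension - degree - 1
    if n_interior < 0:
        raise ValueError("dimension too small for the requested degree")
    lo, hi = x.min(), x.max()
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, probs)
        interior = np.clip(interior, lo + 1e-9 * np.ptp(x), hi - 1e-9 * np.ptp(x))
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()

    xi = _greville(knots, degree)
    d = dimension
    D = np.zeros((d - 2, d))
    for i in range(d - 2):
        h1, h2 = xi[i + 1] - xi[i], xi[i + 2] - xi[i + 1]
        D[i, i] = 1.0 / h1
        D[i, i + 1] = -(1.0 / h1 + 1.0 / h2)
        D[i, i + 2] = 1.0 / h2
    P = D.T @ D
    return B, P, knots


# ---------------------------------------------------------------------------
# Partially linear penalized fit
# ---------------------------------------------------------------------------

@dataclass
class SmoothFit:
    """A fitted partially linear penalized-spline Gaussian model."""

    response: str
    covariate_names: list[str]
    knots: np.ndarray
    degree: int
    coef: np.ndarray              # [linear coefs, constrained spline coefs]
    lam: float
    edf: float                    # trace of the influence matrix
    rss: float
    n: int
    aic: float
    sigma2: float
    _X_names: list[str] = field(default_factory=list, repr=False)
    _Z: np.ndarray | None = field(default=None, repr=False)
    _cov: np.ndarray | None = field(default=None, repr=False)
    _n_lin: int = 0

    def smooth_curve(self, d_grid) -> pd.DataFrame:
        """Evaluate the centered smooth term f(D) on a grid with pointwise
        95% bands (posterior covariance of the penalized fit)."""
        d_grid = np.asarray(d_grid, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        Bg = BSpline.design_matrix(np.clip(d_grid, lo, hi), self.knots, self.degree).toarray()
        C = Bg @ self._Z
        gamma = self.coef[self._n_lin:]
        fit = C @ gamma
        covg = self._cov[self._n_lin:, self._n_lin:]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, covg, C), 0.0))
        return pd.DataFrame({"d": d_grid, "fit": fit,
                             "lo": fit - 1.96 * se, "hi": fit + 1.96 * se})


def _fit_penalized(y, M, P_full, lam):
    A = M.T @ M + lam * P_full
    b = M.T @ y
    coef = np.linalg.solve(A, b)
    fitted = M @ coef
    rss = float(np.sum((y - fitted) ** 2))
    # edf = tr(M (M'M + lam P)^-1 M') = tr((M'M + lam P)^-1 M'M)
    edf = float(np.trace(np.linalg.solve(A, M.T @ M)))
    return coef, rss, edf, A


def gaussian_aic(n: int, rss: float, edf: float) -> float:
    """Gaussian AIC up to an additive constant: n log(RSS/n) + 2 (edf + 1)."""
    return n * np.log(rss / n) + 2.0 * (edf + 1.0)


def fit_pgam(y, X_lin, x_smooth, lam="auto", basis_dim: int = 10, degree: int = 3,
             response: str = "uacr", covariate_names: list[str] | None = None) -> SmoothFit:
    """Fit y = X beta + f(x_smooth) + eps with a penalized B-spline f.

    Minimizes ||y - X beta - B gamma||^2 + lam * gamma' P gamma.  The spline
    block is reparameterized onto the orthogonal complement of the constant
    function (sum-to-zero style constraint) for identifiability against the
    intercept.  ``lam="auto"`` selects the smoothing parameter by GCV,
    n RSS / (n - edf)^2, on a fixed logarithmic grid with ties toward the
    smoother fit.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X_lin, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if X.shape[0] != n or len(x_smooth) != n:
        raise ValueError("dimension mismatch between y, X_lin and x_smooth")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient linear covariate matrix")

    B, P, knots = build_spline_basis(x_smooth, basis_dim, degree)
    # constraint: remove the constant direction (B @ 1 = 1 aliases the intercept)
    d = B.shape[1]
    ones = np.ones((d, 1)) / np.sqrt(d)
    Z = np.linalg.qr(np.eye(d) - ones @ ones.T)[0][:, : d - 1]
    Bz = B @ Z
    Pz = Z.T @ P @ Z
    M = np.hstack([X, Bz])
    p_lin = X.shape[1]
    P_full = np.zeros((M.shape[1], M.shape[1]))
    P_full[p_lin:, p_lin:] = Pz

    if lam == "auto":
        best = None
        for lam_c in GCV_GRID:
            coef, rss, edf, A = _fit_penalized(y, M, P_full, lam_c)
            gcv = n * rss / (n - edf) ** 2
            if best is None or gcv <= best[0] + 1e-12:   # ties -> larger lambda
                best = (gcv, lam_c, coef, rss, edf, A)
        _, lam_v, coef, rss, edf, A = best
    else:
        lam_v = float(lam)
        if lam_v < 0:
            raise ValueError("lam must be >= 0")
        coef, rss, edf, A = _fit_penalized(y, M, P_full, lam_v)

    sigma2 = rss / max(n - edf, 1.0)
    cov = sigma2 * np.linalg.inv(A)      # Bayesian posterior covariance
    names = covariate_names or [f"x{j}" for j in range(p_lin)]
    return SmoothFit(
        response=response, covariate_names=names, knots=knots, degree=degree,
        coef=coef, lam=lam_v, edf=edf, rss=rss, n=n,
        aic=gaussian_aic(n, rss, edf), sigma2=sigma2,
        _X_names=names, _Z=Z, _cov=cov, _n_lin=p_lin)


# ---------------------------------------------------------------------------
# AIC-grid threshold scan
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Result of the 0.2-increment change-point grid search."""

    grid: np.ndarray              # candidate thresholds, ng/mL
    aic: np.ndarray               # per-candidate AIC
    delta: np.ndarray             # per-candidate hinge coefficient estimates
    selected_tau: float           # AIC arg-min (ties toward smaller tau)
    aic_null: float               # covariates + linear D, no threshold
    aic_margin: float             # aic_null - min(aic); > 0 supports a threshold
    has_threshold: bool
    adjustment: str
    log_uacr: bool
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.grid, "aic": self.aic, "delta": self.delta})


def threshold_scan(
    cohort: pd.DataFrame,
    adjust: str = "full",
    grid_low: float = 4.0,
    grid_high: float = 30.0,
    step: float = 0.2,
    log_uacr: bool = False,
    smooth: bool = False,
    basis_dim: int = 10,
) -> ThresholdScan:
    """Scan candidate 25(OH)D thresholds on a 0.2 ng/mL grid by AIC.

    For each candidate tau the Gaussian model
    ``response ~ covariates + alpha*D + delta*(tau - D)_+`` is fitted by
    least squares (``smooth=True`` instead replaces ``alpha*D`` by a
    penalized smooth of D, refitted per candidate).  The grid is clipped to
    the 1st-99th percentile of observed 25(OH)D.  The response is raw UACR
    (mg/g) or, with ``log_uacr=True``, its natural logarithm.
    """
    D = cohort["serum_25ohd"].to_numpy(dtype=float)
    y = cohort["uacr"].to_numpy(dtype=float)
    if log_uacr:
        y = np.log(y)
    lo_sup, hi_sup = np.percentile(D, [1, 99])
    g_lo, g_hi = max(grid_low, lo_sup), min(grid_high, hi_sup)
    if g_lo >= g_hi:
        raise ValueError("threshold grid lies outside the observed 25(OH)D support")
    grid = np.round(np.arange(g_lo, g_hi + step / 2, step), 10)
    if len(grid) < 10:
        raise ValueError(f"threshold grid has only {len(grid)} candidates (>= 10 required)")

    X, _ = build_design(cohort, adjust)
    n = len(y)

    if smooth:
        fit0 = fit_pgam(y, X, D, lam="auto", basis_dim=basis_dim)
        aic_null = fit0.aic
        aics, deltas = np.empty(len(grid)), np.empty(len(grid))
        for i, tau in enumerate(grid):
            hinge = np.clip(tau - D, 0.0, None)
            fit = fit_pgam(y, np.column_stack([X, hinge]), D, lam="auto",
                           basis_dim=basis_dim)
            aics[i] = fit.aic
            deltas[i] = fit.coef[X.shape[1]]
    else:
        Xd = np.column_stack([X, D])
        p = Xd.shape[1] + 1               # + hinge column
        coef0, res0, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        rss0 = float(np.sum((y - Xd @ coef0) ** 2))
        aic_null = gaussian_aic(n, rss0, p - 1)
        aics, deltas = np.empty(len(grid)), np.empty(len(grid))
        for i, tau in enumerate(grid):
            hinge = np.clip(tau - D, 0.0, None)
            M = np.column_stack([Xd, hinge])
            coef, *_ = np.linalg.lstsq(M, y, rcond=None)
            rss = float(np.sum((y - M @ coef) ** 2))
            aics[i] = gaussian_aic(n, rss, p)
            deltas[i] = coef[-1]

    i_best = int(np.argmin(aics))          # argmin takes the first (smallest tau) on ties
    tau_hat = float(grid[i_best])
    margin = float(aic_null - aics[i_best])
    has_threshold = margin > 0.0
    if i_best in (0, len(grid) - 1):
        warnings.warn(
            f"selected threshold {tau_hat} ng/mL lies on the scan boundary; "
            "widen the grid")
    if not has_threshold:
        logger.info("no threshold: best candidate AIC does not beat the "
                    "no-threshold model (margin %.3f)", margin)
    return ThresholdScan(
        grid=grid, aic=aics, delta=deltas, selected_tau=tau_hat,
        aic_null=aic_null, aic_margin=margin, has_threshold=has_threshold,
        adjustment=adjust if isinstance(adjust, str) else "custom",
        log_uacr=log_uacr, n=n)


def plot_threshold_gam(scans, cohort: pd.DataFrame, path, log_uacr: bool = False):
    """Plot the smoothed UACR-difference curve against 25(OH)D with pointwise
    95% bands and a vertical marker at each scan's selected threshold, one
    panel per adjustment set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(scans, ThresholdScan):
        scans = [scans]
    D = cohort["serum_25ohd"].to_numpy(dtype=float)
    y = cohort["uacr"].to_numpy(dtype=float)
    if log_uacr:
        y = np.log(y)
    d_grid = np.linspace(*np.percentile(D, [1, 99]), 200)

    fig, axes = plt.subplots(1, len(scans), figsize=(5 * len(scans), 4),
                             squeeze=False)
    for ax, scan in zip(axes[0], scans):
        X, names = build_design(cohort, scan.adjustment)
        fit = fit_pgam(y, X, D, lam="auto", covariate_names=names)
        curve = fit.smooth_curve(d_grid)
        ax.plot(curve["d"], curve["fit"], color="k")
        ax.plot(curve["d"], curve["lo"], "k--", lw=0.8)
        ax.plot(curve["d"], curve["hi"], "k--", lw=0.8)
        ax.axvline(scan.selected_tau, color="r", lw=1)
        ax.set_title(f"{scan.adjustment} (tau = {scan.selected_tau:.1f} ng/mL)")
        ax.set_xlabel("serum 25(OH)D (ng/mL)")
        ax.set_ylabel("smoothed UACR difference" + (" (log)" if log_uacr else " (mg/g)"))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
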