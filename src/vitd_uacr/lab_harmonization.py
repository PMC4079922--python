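"""Multi-site laboratory harmonization by stratified quantile normalization.

Laboratory results measured on different assay platforms at different
institutions are not directly poolable.  Quantile normalization forces the
per-site distributions to coincide by averaging values of equal rank: each
site's vector is sorted, values at the same rank are averaged across sites,
and each observation is replaced by the rank-average at its own within-site
rank.  To preserve clinical meaning, the stratified variant first partitions
every site's values by the analyte's reference range into below-range,
within-range and above-range strata and normalizes each stratum
independently, so no measurement changes its clinical interpretation.

Conventions where the procedure is under-determined:

* Unequal site sizes: each site's empirical quantile function is linearly
  interpolated onto a common probability grid, averaged across sites, and
  each value is mapped through the averaged quantile function at its own
  (average-rank) plotting position.  For equal sizes without ties this is
  exactly the classical rank-average.
* Ties: tied values receive the mean of the rank-averages their ranks span.
* Boundary crossing: if averaging would push a value across its stratum's
  reference-range boundary it is clamped just inside the stratum, and the
  clamp is logged.
* A stratum empty at one site but populated at another cannot be rank-matched;
  those values pass through unchanged with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceRange",
    "SiteLabPanel",
    "panels_from_frame",
    "panels_to_frame",
    "quantile_normalize",
    "stratified_quantile_normalize",
]

logger = logging.getLogger(__name__)

STRATA = ("below", "within", "above")


@dataclass(frozen=True)
class ReferenceRange:
    """Reference interval of one analyte, in the analyte's units."""

    analyte: str
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"reference range must have lower < upper "
                             f"({self.analyte}: {self.lower}, {self.upper})")

    def stratum_of(self, values) -> np.ndarray:
        """'below' (< lower), 'within' (lower <= x <= upper), 'above' (> upper)."""
        x = np.asarray(values, dtype=float)
        out = np.full(x.shape, "within", dtype=object)
        out[x < self.lower] = "below"
        out[x > self.upper] = "above"
        return out


@dataclass
class SiteLabPanel:
    """One site's measurements of one analyte."""

    site_id: str
    analyte: str
    values: np.ndarray
    reference_range: ReferenceRange | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("panel values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in panel {self.site_id}/{self.analyte}")


def _check_panels(panels: list[SiteLabPanel]) -> None:
    if not panels:
        raise ValueError("no panels given")
    analytes = {p.analyte for p in panels}
    if len(analytes) != 1:
        raise ValueError(f"panels mix analytes: {sorted(analytes)}")
    for p in panels:
        if p.values.size == 0:
            raise ValueError(f"empty panel: {p.site_id}/{p.analyte}")


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Average (mid) ranks, 1-based, ties averaged."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def quantile_normalize(panels: list[SiteLabPanel]) -> list[SiteLabPanel]:
    """Cross-site quantile normalization by rank averaging.

    With equal panel lengths, value i-th smallest at a site is replaced by
    the across-site mean of the i-th smallest values, so all output panels
    share an identical multiset; tied values get the mean of the rank-means
    their ranks span.  Unequal lengths interpolate through a common quantile
    grid (module docstring).  A single panel is returned unchanged with a
    warning; empty panels are an error.
    """
    _check_panels(panels)
    if len(panels) == 1:
        warnings.warn("quantile normalization of a single panel is a no-op")
        return [replace(panels[0], values=panels[0].values.copy())]

    sizes = {p.values.size for p in panels}
    if len(sizes) == 1:
        n = sizes.pop()
        sorted_cols = np.stack([np.sort(p.values) for p in panels])
        rank_means = sorted_cols.mean(axis=0)          # value at rank r (1..n)
        # prefix sums let a tie spanning ranks r..s take mean(rank_means[r-1:s])
        csum = np.concatenate([[0.0], np.cumsum(rank_means)])
        out = []
        for p in panels:
            ranks = _average_ranks(p.values)
            # a mid-rank m over a tie of extent k spans ranks m-(k-1)/2 .. m+(k-1)/2;
            # recover the span from the tie multiplicity
            new_vals = np.empty(n)
            _, inv, cnt = np.unique(p.values, return_inverse=True, return_counts=True)
            k = cnt[inv]
            lo = (ranks - (k - 1) / 2.0).round().astype(int)   # 1-based
            hi = (ranks + (k - 1) / 2.0).round().astype(int)
            new_vals = (csum[hi] - csum[lo - 1]) / (hi - lo + 1)
            out.append(replace(p, values=new_vals))
        return out

    # unequal sizes: common-grid interpolation of the quantile functions
    m = max(sizes)
    grid = np.linspace(0.0, 1.0, m)
    qfuns = []
    for p in panels:
        sv = np.sort(p.values)
        pp = np.linspace(0.0, 1.0, sv.size) if sv.size > 1 else np.array([0.5])
        qfuns.append(np.interp(grid, pp, sv))
    qbar = np.mean(qfuns, axis=0)
    out = []
    for p in panels:
        nv = p.values.size
        ranks = _average_ranks(p.values)
        pos = (ranks - 1.0) / (nv - 1.0) if nv > 1 else np.full(nv, 0.5)
        out.append(replace(p, values=np.interp(pos, grid, qbar)))
    return out


def _clamp_stratum(values: np.ndarray, stratum: str, rr: ReferenceRange,
                   site: str) -> np.ndarray:
    if stratum == "below":
        lim = np.nextafter(rr.lower, -np.inf)
        bad = values >= rr.lower
        clamped = np.where(bad, lim, values)
    elif stratum == "above":
        lim = np.nextafter(rr.upper, np.inf)
        bad = values <= rr.upper
        clamped = np.where(bad, lim, values)
    else:
        bad = (values < rr.lower) | (values > rr.upper)
        clamped = np.clip(values, rr.lower, rr.upper)
    if bad.any():
        logger.warning(
            "clamped %d normalized value(s) back into the %s-range stratum "
            "(site %s, analyte %s)", int(bad.sum()), stratum, site, rr.analyte)
    return clamped


def stratified_quantile_normalize(panels: list[SiteLabPanel]) -> list[SiteLabPanel]:
    """Reference-range-stratified quantile normalization.

    Each panel is partitioned into below-range, within-range and above-range
    strata; strata are quantile-normalized independently across sites, and
    results are reassembled in the original record order.  All panels must
    carry the same reference range.  See the module docstring for the
    empty-stratum fallback and boundary clamping.
    """
    _check_panels(panels)
    ranges = {p.reference_range for p in panels}
    if len(ranges) != 1 or None in ranges:
        raise ValueError("all panels must share one reference range")
    rr = panels[0].reference_range

    strata_masks = [{s: p.reference_range.stratum_of(p.values) == s for s in STRATA}
                    for p in panels]
    new_values = [p.values.copy() for p in panels]

    for s in STRATA:
        counts = [int(m[s].sum()) for m in strata_masks]
        populated = [i for i, c in enumerate(counts) if c > 0]
        if not populated:
            continue
        if len(populated) < len(panels) or len(panels) == 1:
            if 0 < len(populated):
                empty_sites = [panels[i].site_id for i, c in enumerate(counts) if c == 0]
                if empty_sites:
                    warnings.warn(
                        f"stratum {s!r} of analyte {rr.analyte!r} is empty at "
                        f"site(s) {empty_sites}; values at other sites pass "
                        f"through unchanged")
                    continue
        sub = [replace(panels[i], values=panels[i].values[strata_masks[i][s]])
               for i in populated]
        if len(sub) == 1:
            continue  # nothing to rank-match against
        normed = quantile_normalize(sub)
        for i, pn in zip(populated, normed):
            new_values[i][strata_masks[i][s]] = _clamp_stratum(
                pn.values, s, rr, panels[i].site_id)

    return [replace(p, values=v) for p, v in zip(panels, new_values)]


# ---------------------------------------------------------------------------
# Long-format CSV interface
# ---------------------------------------------------------------------------

def panels_from_frame(df: pd.DataFrame, ranges: pd.DataFrame | None = None
                      ) -> list[SiteLabPanel]:
    """Build panels from a long table (site_id, analyte, value), optionally
    attaching reference ranges from a table (analyte, lower, upper)."""
    rr_map = {}
    if ranges is not None:
        for _, row in ranges.iterrows():
            rr_map[row["analyte"]] = ReferenceRange(
                row["analyte"], float(row["lower"]), float(row["upper"]))
    panels = []
    for (site, analyte), grp in df.groupby(["site_id", "analyte"], sort=True):
        panels.append(SiteLabPanel(str(site), str(analyte),
                                   grp["value"].to_numpy(float),
                                   rr_map.get(analyte)))
    return panels


def panels_to_frame(panels: list[SiteLabPanel]) -> pd.DataFrame:
    frames = [pd.DataFrame({"site_id": p.site_id, "analyte": p.analyte,
                            "value": p.values}) for p in panels]
    return pd.concat(frames, ignore_index=True)
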