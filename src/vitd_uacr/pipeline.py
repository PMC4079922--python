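"""End-to-end pipeline: simulate -> normalize -> prepare -> scan -> associate -> report.

Stages exchange plain CSV (with header) and JSON, so each stage can be
re-run from the previous stage's serialized outputs alone, and a manifest
records seeds, the config hash and package versions so identical configs
reproduce identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import category_or, or_table, predicted_probability_curve
from .cohort_prep import apply_exclusions, classify_uae, classify_vitd, descriptive_table
from .gam_threshold import plot_threshold_gam, threshold_scan
from .lab_harmonization import (ReferenceRange, SiteLabPanel,
                                stratified_quantile_normalize)
from .synthetic_cohort import (GeneratorConfig, apply_site_bias, generate_cohort,
                               load_cohort, save_cohort)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

#: 25(OH)D laboratory reference range used for stratified normalization, ng/mL.
VITD_REFERENCE_RANGE = (30.0, 100.0)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "vitd_uacr_out"
    seed: int = 0
    #: path to an existing cohort CSV; when None a cohort is simulated
    input_cohort: str | None = None
    generator: dict = field(default_factory=dict)
    with_site_bias: bool = False
    schemes: list = field(default_factory=lambda: ["quartile", "percentile", "clinical"])
    adjustment_sets: list = field(default_factory=lambda: ["none", "demo", "full"])
    grid_low: float = 4.0
    grid_high: float = 30.0
    step: float = 0.2
    log_uacr: bool = True
    curve_n_boot: int = 200
    make_figures: bool = True
    stages: list = field(default_factory=lambda: [
        "simulate", "normalize", "prepare", "scan", "associate", "report"])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.input_cohort is not None and not Path(self.input_cohort).exists():
            raise ValueError(f"input cohort not found: {self.input_cohort}")
        known = {"simulate", "normalize", "prepare", "scan", "associate", "report"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if not self.stages:
            raise ValueError("no stages enabled")
        for s in self.schemes:
            if s not in ("quartile", "percentile", "clinical"):
                raise ValueError(f"unknown scheme {s!r}")
        GeneratorConfig(**{**self.generator, "seed": self.seed}).validate()

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return a report bundle dict.

    A stage failure halts the run; outputs of completed stages are retained
    and the manifest carries an error marker.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(out)}
    manifest = {
        "package_version": __version__,
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed, "config_hash": config.config_hash(),
        "config": asdict(config), "stages_completed": [],
    }

    try:
        cohort = _stage_simulate(config, out, bundle, manifest)
        cohort = _stage_normalize(config, out, bundle, manifest, cohort)
        retained = _stage_prepare(config, out, bundle, manifest, cohort)
        _stage_scan(config, out, bundle, manifest, retained)
        _stage_associate(config, out, bundle, manifest, retained)
    except Exception as exc:                             # noqa: BLE001 - marker then re-raise
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    if "report" in config.stages:
        manifest["stages_completed"].append("report")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def _stage_simulate(config, out, bundle, manifest):
    if config.input_cohort is not None:
        cohort = load_cohort(config.input_cohort)
        bundle["cohort"] = config.input_cohort
        return cohort
    if "simulate" not in config.stages:
        raise ValueError("no input cohort and the simulate stage is disabled")
    gen_cfg = GeneratorConfig(**{**config.generator, "seed": config.seed})
    cohort = generate_cohort(gen_cfg)
    if config.with_site_bias:
        vals = cohort["serum_25ohd"].to_numpy()
        biased = vals.copy()
        for j in range(gen_cfg.site_count):
            mask = (cohort["site_id"] == f"site{j + 1}").to_numpy()
            biased[mask] = apply_site_bias(vals[mask], gen_cfg.site_biases[j])
        cohort = cohort.assign(serum_25ohd=biased)
    save_cohort(cohort, out / "cohort.csv", gen_cfg)
    logger.info("simulate: %d records", len(cohort))
    bundle["cohort"] = str(out / "cohort.csv")
    manifest["stages_completed"].append("simulate")
    manifest["n_simulated"] = len(cohort)
    return cohort


def _stage_normalize(config, out, bundle, manifest, cohort):
    if "normalize" not in config.stages or not config.with_site_bias:
        return cohort
    lo, hi = VITD_REFERENCE_RANGE
    rr = ReferenceRange("serum_25ohd", lo, hi)
    panels, masks = [], []
    for site, grp in cohort.groupby("site_id", sort=True):
        panels.append(SiteLabPanel(str(site), "serum_25ohd",
                                   grp["serum_25ohd"].to_numpy(float), rr))
        masks.append(grp.index)
    normed = stratified_quantile_normalize(panels)
    vals = cohort["serum_25ohd"].copy()
    for p, idx in zip(normed, masks):
        vals.loc[idx] = p.values
    cohort = cohort.assign(serum_25ohd=vals)
    cohort.to_csv(out / "cohort_normalized.csv", index=False)
    logger.info("normalize: harmonized serum_25ohd across %d sites", len(panels))
    bundle["cohort_normalized"] = str(out / "cohort_normalized.csv")
    manifest["stages_completed"].append("normalize")
    return cohort


def _stage_prepare(config, out, bundle, manifest, cohort):
    if "prepare" not in config.stages:
        return cohort
    retained, log = apply_exclusions(cohort)
    retained = retained.assign(
        uae_status=classify_uae(retained["uacr"].to_numpy(float)),
        vitd_clinical=classify_vitd(retained["serum_25ohd"].to_numpy(float), "clinical"),
    )
    retained.to_csv(out / "retained.csv", index=False)
    (out / "exclusion_log.json").write_text(log.to_json())
    table1 = descriptive_table(
        retained.drop(columns=["vitd_clinical"]), "uae_status")
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    logger.info("prepare: input %d -> retained %d (union excluded %d)",
                log.n_input, log.n_retained, log.n_excluded_union)
    bundle.update(retained=str(out / "retained.csv"),
                  exclusion_log=str(out / "exclusion_log.json"),
                  table1=str(out / "table1.tsv"),
                  n_retained=log.n_retained,
                  n_excluded_union=log.n_excluded_union)
    manifest["stages_completed"].append("prepare")
    manifest["n_retained"] = log.n_retained
    manifest["n_excluded_union"] = log.n_excluded_union
    return retained


def _stage_scan(config, out, bundle, manifest, retained):
    if "scan" not in config.stages:
        return
    scans = []
    selected = {}
    tables = []
    for adj in config.adjustment_sets:
        scan = threshold_scan(retained, adjust=adj, grid_low=config.grid_low,
                              grid_high=config.grid_high, step=config.step,
                              log_uacr=config.log_uacr)
        scans.append(scan)
        selected[adj] = {"tau": scan.selected_tau, "aic_margin": scan.aic_margin,
                         "has_threshold": scan.has_threshold}
        t = scan.to_frame()
        t.insert(0, "adjustment", adj)
        tables.append(t)
        logger.info("scan[%s]: tau = %.1f ng/mL (AIC margin %.2f)",
                    adj, scan.selected_tau, scan.aic_margin)
    pd.concat(tables, ignore_index=True).to_csv(out / "scan_table.csv", index=False)
    (out / "threshold.json").write_text(json.dumps(selected, indent=2))
    if config.make_figures:
        plot_threshold_gam(scans, retained, out / "threshold.png",
                           log_uacr=config.log_uacr)
        bundle["threshold_figure"] = str(out / "threshold.png")
    bundle.update(scan_table=str(out / "scan_table.csv"),
                  threshold=str(out / "threshold.json"),
                  selected_thresholds=selected)
    manifest["stages_completed"].append("scan")
    manifest["selected_thresholds"] = selected


def _stage_associate(config, out, bundle, manifest, retained):
    if "associate" not in config.stages:
        return
    frames = []
    for scheme in config.schemes:
        for adjust in ("none", "full"):
            frames.append(or_table(category_or(retained, scheme, adjust=adjust)))
    ors = pd.concat(frames, ignore_index=True)
    ors.to_csv(out / "or_table.csv", index=False)
    curve = predicted_probability_curve(
        retained, adjust="full", n_boot=config.curve_n_boot, seed=config.seed)
    curve.to_frame().to_csv(out / "curve.csv", index=False)
    if config.make_figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve.grid, curve.prob, "k-")
        ax.plot(curve.grid, curve.lo, "k--", lw=0.8)
        ax.plot(curve.grid, curve.hi, "k--", lw=0.8)
        ax.set_xlabel("serum 25(OH)D (ng/mL)")
        ax.set_ylabel("predicted probability of high-normal UAE")
        fig.tight_layout()
        fig.savefig(out / "curve.png", dpi=120)
        plt.close(fig)
        bundle["curve_figure"] = str(out / "curve.png")
    bundle.update(or_table=str(out / "or_table.csv"), curve=str(out / "curve.csv"))
    manifest["stages_completed"].append("associate")
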