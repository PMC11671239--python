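"""End-to-end analysis runs.

``run_pipeline`` executes the full graph — generate or load a cohort, build
the connectome, compute the five feature tables, predict the score from
each with cross-validated SVR (optionally with a permutation null), and run
the mediation analysis — writing every stage's output under one run
directory together with the resolved configuration, so any number is
traceable to (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cohort_io
from .connectome import build_connectome
from .errors import ConfigError, DataError
from .features import (
    FeatureTable,
    alff_table,
    degree_centrality,
    drop_undefined_rois,
    gmv_table,
    structure_function_coupling,
)
from .mediation import mediate
from .prediction import CVConfig, compare_features, permutation_test, run_cv
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("sfcoupling")

COVARIATE_COLUMNS = ("age", "sex", "motion")


@dataclass
class RunConfig:
    """Fully serializable configuration of one end-to-end run."""

    out_dir: str = "sfc_run"
    cohort_dir: str | None = None  # load an existing cohort ...
    synthetic: SyntheticConfig | None = None  # ... or generate one
    write_cohort: bool = True
    cohort_format: str = "tsv"
    # connectome
    removal_fraction: float = 0.30
    sc_normalization: str = "divide_by_volumes"
    threshold_mode: str = "remove_top"
    # features
    min_edges: int = 3
    fdc_edges: str = "structural"
    alff_band: tuple[float, float] = (0.01, 0.1)
    # prediction
    cv: CVConfig = field(default_factory=CVConfig)
    features: tuple[str, ...] = ("coupling", "alff", "sdc", "fdc", "gmv")
    covariates: tuple[str, ...] = COVARIATE_COLUMNS
    with_permutation: bool = False
    # mediation: x feature averaged over ROIs -> m (coupling) -> score
    mediation_x: str = "alff"
    mediation_rois: tuple[str, ...] | None = None  # None = most-predictive set
    n_boot: int = 5000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "cv" in raw and raw["cv"] is not None and not isinstance(raw["cv"], CVConfig):
            raw["cv"] = CVConfig(**raw["cv"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("features", "covariates", "mediation_rois", "alff_band"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def _covariate_matrix(records, names) -> np.ndarray | None:
    if not names:
        return None
    cols = []
    for name in names:
        if name not in COVARIATE_COLUMNS:
            raise ConfigError(f"unknown covariate {name!r}; choose from {COVARIATE_COLUMNS}")
        cols.append([float(getattr(r, name)) for r in records])
    return np.array(cols).T


def compute_feature_tables(
    records, cc, config: RunConfig, sampling_interval: float | None = None
) -> list[FeatureTable]:
    """All five feature tables for a cohort, in config order."""
    labels = cc.roi_labels
    ids = [r.subject_id for r in records]
    tables = {}
    if "coupling" in config.features:
        tables["coupling"] = structure_function_coupling(cc, min_edges=config.min_edges)
    if "alff" in config.features:
        if sampling_interval is not None:
            dt = sampling_interval
        else:
            dt = config.synthetic.sampling_interval if config.synthetic else 2.0
        tables["alff"] = alff_table(records, dt, band=config.alff_band, roi_labels=labels)
    if "sdc" in config.features:
        tables["sdc"] = degree_centrality(cc, "structural")
    if "fdc" in config.features:
        tables["fdc"] = degree_centrality(cc, "functional", fdc_edges=config.fdc_edges)
    if "gmv" in config.features:
        frame = pd.DataFrame(np.vstack([r.gmv for r in records]), index=ids, columns=labels)
        tables["gmv"] = gmv_table(frame, subject_ids=ids, roi_labels=labels)
    return [tables[name] for name in config.features if name in tables]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setLevel(config.log_level)
    log.addHandler(fh)
    (out / "resolved_config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True, default=str)
    )
    try:
        return _run_stages(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _stage(name):
    log.info("stage %s", name)
    return time.perf_counter()


def _done(name, t0):
    log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)


def _run_stages(config: RunConfig, out: Path) -> Path:
    t0 = _stage("cohort")
    sampling_interval = None
    if config.synthetic is not None:
        records = generate_cohort(config.synthetic)
        if config.write_cohort:
            cohort_io.write_cohort(
                records, out / "cohort", config.synthetic, fmt=config.cohort_format
            )
    elif config.cohort_dir is not None:
        records, manifest = cohort_io.read_cohort(config.cohort_dir)
        sampling_interval = (manifest.get("config") or {}).get("sampling_interval")
    else:
        raise ConfigError("config needs either `synthetic` or `cohort_dir`")
    _done("cohort", t0)

    t0 = _stage("connectome")
    cc = build_connectome(
        records,
        removal_fraction=config.removal_fraction,
        sc_normalization=config.sc_normalization,
        threshold_mode=config.threshold_mode,
    )
    cdir = out / "connectome"
    cdir.mkdir(exist_ok=True)
    mask = pd.DataFrame(
        cc.edge_mask.astype(int), index=cc.roi_labels, columns=cc.roi_labels
    )
    mask.to_csv(cdir / "edge_mask.tsv", sep="\t")
    _done("connectome", t0)

    t0 = _stage("features")
    tables = compute_feature_tables(records, cc, config, sampling_interval=sampling_interval)
    tables, dropped = drop_undefined_rois(tables)
    fdir = out / "features"
    fdir.mkdir(exist_ok=True)
    for t in tables:
        t.to_frame().rename_axis("subject_id").to_csv(
            fdir / f"{t.name}.tsv", sep="\t", float_format="%.10g"
        )
    if dropped:
        log.info("dropped %d ROI(s) with undefined coupling: %s", len(dropped), dropped)
    (fdir / "dropped_rois.json").write_text(json.dumps(dropped, sort_keys=True))
    _done("features", t0)

    t0 = _stage("prediction")
    scores = np.array([r.score for r in records])
    cov = _covariate_matrix(records, config.covariates)
    report, results = compare_features(tables, scores, cov, config.cv)
    pdir = out / "predict"
    pdir.mkdir(exist_ok=True)
    perm_ps: dict[str, float] = {}
    for t in tables:
        res = results[t.name]
        sub = pdir / t.name
        sub.mkdir(exist_ok=True)
        res.roi_summary.sort_values(
            ["selected_count", "total_weight"], ascending=False
        ).to_csv(sub / "roi_summary.tsv", sep="\t", index=False, float_format="%.10g")
        metrics = dict(res.metrics)
        metrics["most_predictive"] = res.most_predictive
        metrics["degenerate"] = res.degenerate
        if config.with_permutation:
            perm = permutation_test(t, scores, cov, config.cv, observed=res)
            metrics["permutation_p"] = perm.p_value
            perm_ps[t.name] = perm.p_value
            np.savetxt(sub / "null_distribution.tsv", perm.null_rhos, fmt="%.10g")
        (sub / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    report.to_csv(pdir / "report.tsv", sep="\t", index=False, float_format="%.10g")
    _done("prediction", t0)

    t0 = _stage("mediation")
    med_result = None
    med_rois = list(config.mediation_rois) if config.mediation_rois else None
    coupling_res = results.get("coupling")
    if med_rois is None and coupling_res is not None:
        med_rois = coupling_res.most_predictive
    by_name = {t.name: t for t in tables}
    if med_rois and config.mediation_x in by_name and "coupling" in by_name:
        xt, mt = by_name[config.mediation_x], by_name["coupling"]
        missing = [r for r in med_rois if r not in mt.roi_labels]
        if missing:
            raise DataError(f"mediation ROIs not in feature tables: {missing}")
        cols = [mt.roi_labels.index(r) for r in med_rois]
        x = xt.values[:, cols].mean(axis=1)
        m = mt.values[:, cols].mean(axis=1)
        med_result = mediate(
            x, m, scores, covariates=None, n_boot=config.n_boot, seed=config.cv.seed
        )
        payload = med_result.to_dict()
        payload.update({"x_feature": config.mediation_x, "rois": med_rois})
        (out / "mediation.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    else:
        log.info("mediation skipped: no ROI set available")
        (out / "mediation.json").write_text(json.dumps({"skipped": True}))
    _done("mediation", t0)

    _write_report(out, report, results, perm_ps, med_result, med_rois, config)
    return out


def _write_report(out, report, results, perm_ps, med_result, med_rois, config) -> None:
    lines = ["# Structure-function coupling analysis report", ""]
    lines += ["## Prediction performance per feature", ""]
    lines.append("```")
    lines.append(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    lines.append("```")
    lines.append("")
    if perm_ps:
        lines += ["## Permutation p-values", ""]
        for name, p in sorted(perm_ps.items()):
            lines.append(f"- {name}: p = {p:.4g}")
        lines.append("")
    best = report.iloc[0]["feature"]
    res = results[best]
    lines += [f"## ROI summary, best feature ({best})", ""]
    top = res.roi_summary[res.roi_summary.selected_count > 0].sort_values(
        ["selected_count", "total_weight"], ascending=False
    )
    lines.append("```")
    lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    lines.append("```")
    lines.append("")
    if med_result is not None:
        d = med_result.to_dict()
        lines += [
            "## Mediation",
            "",
            f"x = mean {config.mediation_x} over {med_rois}; "
            "m = mean coupling over the same ROIs; y = score.",
            "",
            f"- a = {d['a']:.4f} (p = {d['p_a']:.4g}), b = {d['b']:.4f} (p = {d['p_b']:.4g})",
            f"- c = {d['c']:.4f} (p = {d['p_c']:.4g}), c' = {d['c_prime']:.4f} (p = {d['p_c_prime']:.4g})",
            f"- indirect = {d['indirect']:.4f}, partially standardized = {d['ps_indirect']:.4f}",
            f"- {int(d['ci_level'] * 100)}% bootstrap CI: [{d['ci_lower']:.4f}, {d['ci_upper']:.4f}]",
            f"- full mediation label: {d['full_mediation']}",
            "",
        ]
    (out / "report.md").write_text("\n".join(lines))
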