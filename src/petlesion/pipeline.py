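"""End-to-end evaluation pipeline: simulate → segment/read → match → evaluate.

One :class:`RunConfig` drives a full synthetic evaluation run: a cohort of
phantoms is generated, model lesion sets are produced either by the
simulated reader or by the rule-based segmenter, expert/model sets are put
in one-to-one correspondence per patient, and the detection and agreement
metric battery is computed.  All randomness derives from a single seed, so
a run is byte-reproducible.

Stages communicate through plain data (LesionSets, DataFrames, dicts) and,
when an output directory is given, through on-disk artifacts (NIfTI, CSV,
JSON) so each stage can be re-run or replaced in isolation — the
evaluation half accepts externally produced label maps and lesion tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import (
    SITES,
    Lesion,
    LesionSet,
    lesion_table,
    write_label_map,
    write_suv_volume,
)
from .correspondence import CorrespondenceResult, classify_detections, merge_to_one_to_one
from .metrics import (
    AgreementReport,
    agreement_with_icc,
    cohort_overestimation,
    matched_lesion_sizes,
    patient_lesion_counts,
    pr_sweep,
    precision_recall,
    tumor_burden,
)
from .segmenter import SegmenterConfig, segment_volume
from .synthetic import (
    Phantom,
    ReaderSpec,
    generate_phantom,
    regime_presets,
    sample_cohort_specs,
    simulate_model_output,
)

__all__ = ["RunConfig", "run_pipeline", "render_report", "evaluate_correspondences"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``model_source`` selects how model lesion sets are produced:
    "reader" uses the simulated reader (scored lesions); "segmenter" runs
    the rule-based segmenter on the blurred phantom, assigning score 1.0
    to every emitted lesion (the malignancy classifier is out of scope, so
    segmenter output is treated as uniformly suspicious).
    """

    n_patients: int = 10
    model_source: str = "reader"  # "reader" | "segmenter"
    reader: ReaderSpec = field(default_factory=ReaderSpec)
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    min_overlap_voxels: int = 1
    score_threshold: float = 0.5
    thresholds: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 0.95, 20), 4))
    alpha: float = 0.05
    phantom_shape: tuple[int, int, int] = (48, 48, 48)
    phantom_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.model_source not in ("reader", "segmenter"):
            raise ValueError("model_source must be 'reader' or 'segmenter'")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def _config_hash(config: RunConfig) -> str:
    def default(o: Any) -> Any:
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o).__name__)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _with_uniform_score(ls: LesionSet, score: float = 1.0) -> LesionSet:
    lesions = [dataclasses.replace(l, score=score) for l in ls.lesions]
    return LesionSet(lesions=lesions, label_map=ls.label_map, patient_id=ls.patient_id)


def _report_to_dict(rep: AgreementReport) -> dict[str, Any]:
    return {
        "axis": rep.axis,
        "n": rep.n,
        "median_diff": rep.median_diff,
        "mad": rep.mad,
        "mrpd": rep.mrpd,
        "marpd": rep.marpd,
        "icc": rep.icc,
        "icc_ci_low": rep.icc_ci_low,
        "icc_ci_high": rep.icc_ci_high,
    }


def evaluate_correspondences(
    correspondences: Sequence[CorrespondenceResult],
    thresholds: Sequence[float],
    score_threshold: float = 0.5,
    alpha: float = 0.05,
) -> dict[str, Any]:
    """Metric battery over per-patient correspondences.

    Returns the detection table (overall + per site at the working
    threshold), the three agreement rows (lesion counts, matched lesion
    sizes, tumor burden), the PR sweep, and cohort-level overestimation
    percentages for counts and burden.
    """
    counts = [classify_detections(c, score_threshold) for c in correspondences]
    detection_rows = []
    tp = sum(c.tp for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    overall = precision_recall(tp, fp, fn, site="all", threshold=score_threshold)
    detection_rows.append(overall)
    for site in SITES:
        tps = sum(c.per_site[site][0] for c in counts)
        fps = sum(c.per_site[site][1] for c in counts)
        fns = sum(c.per_site[site][2] for c in counts)
        detection_rows.append(
            precision_recall(tps, fps, fns, site=site, threshold=score_threshold)
        )

    agreement: dict[str, AgreementReport] = {}
    counts_sample = patient_lesion_counts(correspondences, score_threshold)
    # per-patient relative metrics need nonzero expert counts; expert sets
    # always have >= 1 lesion in generated cohorts, but guard anyway
    agreement["lesion_count"] = agreement_with_icc(
        counts_sample, alpha=alpha,
        percentages=all(v > 0 for v in counts_sample.expert_values),
    )
    try:
        sizes = matched_lesion_sizes(correspondences, score_threshold)
        agreement["lesion_size"] = agreement_with_icc(sizes, alpha=alpha)
    except ValueError:
        pass
    burden = tumor_burden(correspondences, score_threshold)
    agreement["tumor_burden"] = agreement_with_icc(
        burden, alpha=alpha,
        percentages=all(v > 0 for v in burden.expert_values),
    )

    sweep = pr_sweep(correspondences, thresholds)

    n_expert = sum(len(c.merged_expert) for c in correspondences)
    n_susp = tp + fp
    overest = {
        "lesion_count_pct": cohort_overestimation(n_expert, n_susp) if n_expert else None,
        "tumor_burden_pct": (
            cohort_overestimation(sum(burden.expert_values), sum(burden.model_values))
            if sum(burden.expert_values) > 0
            else None
        ),
    }
    return {
        "detection": [dataclasses.asdict(m) for m in detection_rows],
        "agreement": {k: _report_to_dict(v) for k, v in agreement.items()},
        "pr_curves": sweep.to_dict(orient="records"),
        "cohort_overestimation": overest,
        "n_patients": len(correspondences),
        "expert_lesions": n_expert,
        "suspicious_model_lesions": n_susp,
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full simulate → model → match → evaluate chain."""
    rng = np.random.default_rng(config.seed)
    phantom_seed = int(rng.integers(0, 2**31 - 1))
    reader_seed = int(rng.integers(0, 2**31 - 1))

    specs = sample_cohort_specs(
        n_patients=config.n_patients,
        seed=phantom_seed,
        shape=config.phantom_shape,
        spacing=config.phantom_spacing,
    )
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    correspondences: list[CorrespondenceResult] = []
    expert_sets: list[LesionSet] = []
    model_sets: list[LesionSet] = []
    for i, spec in enumerate(specs):
        pid = f"p{i:03d}"
        phantom = generate_phantom(spec, patient_id=pid)
        expert = phantom.expert_lesion_set()
        if config.model_source == "reader":
            model = simulate_model_output(
                expert, phantom.site_map, config.reader, phantom.volume,
                seed=(reader_seed + i) % 2**31,
            )
        else:
            model = segment_volume(
                phantom.volume, phantom.blood_pool_mask, phantom.site_map,
                config.segmenter, patient_id=pid,
            )
            model = _with_uniform_score(model, 1.0)
        if out_dir:
            write_suv_volume(phantom.volume, out_dir / f"{pid}_suv.nii.gz")
            write_label_map(phantom.expert_labels, out_dir / f"{pid}_expert.nii.gz")
            write_label_map(model.label_map, out_dir / f"{pid}_model.nii.gz")
        expert_sets.append(expert)
        model_sets.append(model)
        correspondences.append(
            merge_to_one_to_one(expert, model, config.min_overlap_voxels)
        )

    report = evaluate_correspondences(
        correspondences,
        thresholds=config.thresholds,
        score_threshold=config.score_threshold,
        alpha=config.alpha,
    )
    report["config_hash"] = _config_hash(config)
    report["seed"] = config.seed
    if out_dir:
        lesion_table(expert_sets + model_sets).to_csv(out_dir / "lesions.csv", index=False)
        (out_dir / "metrics.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        render_report(report, out_dir)
    return report


def _md_table(df: pd.DataFrame) -> str:
    def fmt(v: Any) -> str:
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            return ""
        if isinstance(v, float):
            return f"{v:.2f}"
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def render_report(report: dict[str, Any], out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Render the metrics report as CSV + Markdown tables.

    Emits a detection table (location, recall, precision) and an agreement
    table with the five metric columns (median difference, MAD, MRPD,
    MARPD, ICC with CI), plus the PR curve data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    det_rows = []
    for m in report["detection"]:
        det_rows.append(
            {
                "location": "All" if m["site"] == "all" else m["site"],
                "recall_pct": m["recall"],
                "precision_pct": m["precision"],
                "tp": m["tp"],
                "fp": m["fp"],
                "fn": m["fn"],
            }
        )
    detection = pd.DataFrame(det_rows)
    if detection.empty:
        detection = pd.DataFrame(
            [{"location": "no lesions", "recall_pct": None, "precision_pct": None,
              "tp": 0, "fp": 0, "fn": 0}]
        )

    agr_rows = []
    axis_names = {
        "lesion_count": "Lesion detection",
        "lesion_size": "Lesion size [cc]",
        "tumor_burden": "Tumor burden [cc]",
    }
    for key, name in axis_names.items():
        rep = report["agreement"].get(key)
        if rep is None:
            agr_rows.append({"axis": name, "median_difference": None, "mad": None,
                             "mrpd_pct": None, "marpd_pct": None, "icc_95ci": "no lesions"})
            continue
        ci = (
            f"{rep['icc']:.2f} ({rep['icc_ci_low']:.2f}-{rep['icc_ci_high']:.2f})"
            if rep["icc"] is not None and rep["icc_ci_low"] is not None
            else (f"{rep['icc']:.2f}" if rep["icc"] is not None else "n/a")
        )
        agr_rows.append(
            {
                "axis": name,
                "median_difference": rep["median_diff"],
                "mad": rep["mad"],
                "mrpd_pct": rep["mrpd"],
                "marpd_pct": rep["marpd"],
                "icc_95ci": ci,
            }
        )
    agreement = pd.DataFrame(agr_rows)
    curves = pd.DataFrame(report["pr_curves"])

    detection.to_csv(out_dir / "detection_table.csv", index=False)
    agreement.to_csv(out_dir / "agreement_table.csv", index=False)
    curves.to_csv(out_dir / "pr_curves.csv", index=False)

    md = ["# Evaluation report", "", "## Detection (per location)", "",
          _md_table(detection), "", "## Agreement", "",
          _md_table(agreement), ""]
    over = report.get("cohort_overestimation", {})
    if over:
        md += [
            "## Cohort totals",
            "",
            f"- Lesion count overestimation: {over.get('lesion_count_pct')}",
            f"- Tumor burden overestimation: {over.get('tumor_burden_pct')}",
            "",
        ]
    (out_dir / "report.md").write_text("\n".join(md))
    return {"detection": detection, "agreement": agreement, "pr_curves": curves}
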