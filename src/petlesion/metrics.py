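"""Detection and agreement metrics for lesion-level evaluation.

Covers the standard battery for comparing an automated reader against an
expert reference after lesion correspondence:

* precision = 100·TP/(TP+FP) and recall (sensitivity) = 100·TP/(TP+FN),
  overall, stratified by anatomical site, and swept over the model's
  probability threshold (precision–recall curves);
* paired agreement on counts, sizes and metabolic tumor burden: median
  difference, median absolute difference (MAD), median relative percentage
  difference (MRPD) and median absolute relative percentage difference
  (MARPD), all with the expert value in the denominator and the sign
  convention model − expert;
* the intraclass correlation coefficient ICC(3,1) — two-way mixed effects,
  single rater, consistency (Shrout–Fleiss) — with its F-based 95 % CI.

Metabolic tumor burden (TB) is the per-patient sum of segmented lesion
volumes in cc; the model's TB estimate includes its false-positive
volumes, since that is what an automated burden readout would report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import SITES, LesionSet
from .correspondence import CorrespondenceResult, classify_detections

__all__ = [
    "DetectionMetrics",
    "PairedSample",
    "AgreementReport",
    "precision_recall",
    "pr_sweep",
    "paired_agreement",
    "icc_3_1",
    "matched_lesion_sizes",
    "patient_lesion_counts",
    "tumor_burden",
    "cohort_overestimation",
]


@dataclass(frozen=True)
class DetectionMetrics:
    """Lesion-level detection counts and percentages for one stratum."""

    tp: int
    fp: int
    fn: int
    precision: float | None  # percent; None when TP+FP == 0
    recall: float | None  # percent; None when TP+FN == 0
    site: str = "all"
    threshold: float = 0.5


def precision_recall(
    tp: int, fp: int, fn: int, site: str = "all", threshold: float = 0.5
) -> DetectionMetrics:
    """Precision and recall in percent; undefined ratios are None, not 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    return DetectionMetrics(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
                            site=site, threshold=threshold)


def pr_sweep(
    correspondences: "CorrespondenceResult | Iterable[CorrespondenceResult]",
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Precision/recall per site across probability thresholds.

    One correspondence (or one per patient) is classified at every
    threshold; counts are pooled over patients before computing the
    percentages.  Returns tidy rows (threshold, site, tp, fp, fn,
    precision, recall) — the data behind per-site PR curves.
    """
    if len(thresholds) == 0:
        raise ValueError("threshold list is empty")
    if isinstance(correspondences, CorrespondenceResult):
        correspondences = [correspondences]
    correspondences = list(correspondences)
    rows = []
    for t in thresholds:
        counts = [classify_detections(c, t) for c in correspondences]
        strata: dict[str, tuple[int, int, int]] = {
            "all": (
                sum(c.tp for c in counts),
                sum(c.fp for c in counts),
                sum(c.fn for c in counts),
            )
        }
        for site in SITES:
            strata[site] = tuple(
                sum(c.per_site[site][k] for c in counts) for k in range(3)
            )
        for site, (tp, fp, fn) in strata.items():
            m = precision_recall(tp, fp, fn, site=site, threshold=t)
            rows.append(
                {
                    "threshold": t,
                    "site": site,
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "precision": m.precision,
                    "recall": m.recall,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedSample:
    """Paired expert/model quantities for one comparison axis."""

    expert_values: tuple[float, ...]
    model_values: tuple[float, ...]
    axis: str  # lesion_count | lesion_size | tumor_burden
    unit: str  # "lesions" | "cc"

    def __post_init__(self) -> None:
        if len(self.expert_values) != len(self.model_values):
            raise ValueError("paired sample lengths differ")
        if len(self.expert_values) < 1:
            raise ValueError("paired sample is empty")

    @property
    def n(self) -> int:
        return len(self.expert_values)


@dataclass
class AgreementReport:
    """Median-based agreement metrics plus ICC(3,1) for one paired sample."""

    axis: str
    n: int
    median_diff: float
    mad: float
    mrpd: float | None  # percent
    marpd: float | None  # percent
    icc: float | None = None
    icc_ci_low: float | None = None
    icc_ci_high: float | None = None


def paired_agreement(sample: PairedSample, percentages: bool = True) -> AgreementReport:
    """Median difference, MAD, MRPD and MARPD for a paired sample.

    Differences are model − expert; relative metrics divide by the expert
    value (which must be nonzero when percentages are requested).
    """
    e = np.asarray(sample.expert_values, dtype=float)
    m = np.asarray(sample.model_values, dtype=float)
    d = m - e
    mrpd = marpd = None
    if percentages:
        zero = np.nonzero(e == 0)[0]
        if zero.size:
            raise ValueError(
                f"expert value is zero at index {int(zero[0])}; "
                "relative percentage metrics undefined"
            )
        rel = 100.0 * d / e
        mrpd = float(np.median(rel))
        marpd = float(np.median(np.abs(rel)))
    return AgreementReport(
        axis=sample.axis,
        n=sample.n,
        median_diff=float(np.median(d)),
        mad=float(np.median(np.abs(d))),
        mrpd=mrpd,
        marpd=marpd,
    )


def icc_3_1(
    sample: PairedSample, alpha: float = 0.05
) -> tuple[float | None, float | None, float | None]:
    """ICC(3,1): two-way mixed effects, single rater, consistency, with CI.

    With subjects mean square MS_R and residual mean square MS_E from the
    two-way (subject × rater) decomposition and k = 2 raters,
    ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E); the confidence interval is
    the standard F-based one at level 1 − alpha.  Returns (icc, lo, hi),
    or (None, None, None) when both raters have zero variance.
    """
    import pingouin as pg

    if sample.n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    e = np.asarray(sample.expert_values, dtype=float)
    m = np.asarray(sample.model_values, dtype=float)
    if np.var(e) == 0 and np.var(m) == 0:
        import warnings

        warnings.warn("zero variance in both raters; ICC undefined", stacklevel=2)
        return None, None, None
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(sample.n), 2),
            "rater": ["expert"] * sample.n + ["model"] * sample.n,
            "value": np.concatenate([e, m]),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="value"
        ).set_index("Type")
    row = res.loc["ICC(C,1)" if "ICC(C,1)" in res.index else "ICC3"]
    icc = float(row["ICC"])
    if not math.isfinite(icc):
        return None, None, None
    # Unrounded F-based CI: F = MS_R/MS_E with df1 = n-1, df2 = (n-1)(k-1);
    # bounds (F/Fcrit - 1)/(F/Fcrit + k - 1) with the appropriate Fcrit.
    from scipy import stats as _stats

    k = 2
    f_obs = float(row["F"])
    df1 = int(row["df1"])
    df2 = int(row["df2"])
    f_upper = _stats.f.ppf(1 - alpha / 2, df1, df2)
    f_lower = _stats.f.ppf(1 - alpha / 2, df2, df1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fl = f_obs / f_upper
        fu = f_obs * f_lower
        lo = (fl - 1.0) / (fl + k - 1.0)
        hi = (fu - 1.0) / (fu + k - 1.0)
    icc = min(icc, 1.0)
    if not (math.isfinite(lo) and math.isfinite(hi)):
        return icc, None, None
    return icc, float(min(lo, 1.0)), float(min(hi, 1.0))


def agreement_with_icc(sample: PairedSample, alpha: float = 0.05,
                       percentages: bool = True) -> AgreementReport:
    """Full agreement row: median metrics plus ICC(3,1) with CI."""
    rep = paired_agreement(sample, percentages=percentages)
    if sample.n >= 3:
        rep.icc, rep.icc_ci_low, rep.icc_ci_high = icc_3_1(sample, alpha=alpha)
    return rep


def matched_lesion_sizes(
    correspondences: Iterable[CorrespondenceResult], threshold: float = 0.5
) -> PairedSample:
    """Per-lesion (expert cc, model cc) for TP pairs at a threshold.

    Only lesions detected by both readers contribute; one entry per
    surviving pair, pooled over patients.
    """
    e_vals: list[float] = []
    m_vals: list[float] = []
    for c in correspondences:
        counts = classify_detections(c, threshold)
        for eid, mid in counts.tp_pairs:
            e_vals.append(c.merged_expert.by_id[eid].volume_cc)
            m_vals.append(c.merged_model.by_id[mid].volume_cc)
    if not e_vals:
        raise ValueError("no matched lesions at this threshold")
    return PairedSample(tuple(e_vals), tuple(m_vals), axis="lesion_size", unit="cc")


def patient_lesion_counts(
    correspondences: Iterable[CorrespondenceResult], threshold: float = 0.5
) -> PairedSample:
    """Per-patient (expert lesion count, suspicious model lesion count)."""
    e_vals = []
    m_vals = []
    for c in correspondences:
        e_vals.append(float(len(c.merged_expert)))
        m_vals.append(
            float(sum(1 for l in c.merged_model.lesions if (l.score or 0.0) >= threshold))
        )
    return PairedSample(tuple(e_vals), tuple(m_vals), axis="lesion_count", unit="lesions")


def tumor_burden(
    correspondences: Iterable[CorrespondenceResult], threshold: float = 0.5
) -> PairedSample:
    """Per-patient metabolic tumor burden (sum of lesion volumes, cc).

    The model burden sums all suspicious lesions — false positives
    included, as an automated burden readout has no way to exclude them.
    """
    e_vals = []
    m_vals = []
    for c in correspondences:
        e_vals.append(c.merged_expert.total_volume_cc())
        m_vals.append(
            float(
                sum(
                    l.volume_cc
                    for l in c.merged_model.lesions
                    if (l.score or 0.0) >= threshold
                )
            )
        )
    return PairedSample(tuple(e_vals), tuple(m_vals), axis="tumor_burden", unit="cc")


def cohort_overestimation(expert_total: float, model_total: float) -> float:
    """Percent over-/under-estimation of a cohort total: 100·(model−expert)/expert."""
    if expert_total <= 0:
        raise ValueError("expert total must be positive")
    return 100.0 * (model_total - expert_total) / expert_total
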