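"""Merge-based one-to-one correspondence between expert and model lesions.

Automated segmenters often fragment one physical lesion into several
components, and conversely a single model component can cover several
reference lesions.  To compare lesion counts and sizes fairly, both sides
are first reduced to a one-to-one correspondence: any group of two or more
lesions on one side whose only overlap partner is one and the same lesion
on the other side is merged into a single lesion (voxel union; volume
summed; SUVmax, SUVpeak and score take the max over constituents).  The
rule is applied symmetrically and iterated to a fixed point.  Residual
many-to-many overlap components are resolved by a greedy one-to-one
assignment in descending shared-voxel order.

Classification then follows the usual lesion-level convention: a paired
model lesion whose score passes the suspiciousness threshold is a true
positive (TP); an unpaired suspicious model lesion is a false positive
(FP); an expert lesion without a surviving suspicious partner is a false
negative (FN).  Sub-threshold ("benign") model lesions take part in the
merging but are removed at classification time, so one correspondence can
be reused across a whole threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelMap, Lesion, LesionSet, SITES

__all__ = [
    "OverlapMatrix",
    "MergeEvent",
    "CorrespondenceResult",
    "DetectionCounts",
    "overlap_matrix",
    "merge_to_one_to_one",
    "classify_detections",
]


@dataclass(frozen=True)
class OverlapMatrix:
    """Shared-voxel counts between expert (rows) and model (columns) lesions."""

    expert_ids: tuple[int, ...]
    model_ids: tuple[int, ...]
    counts: np.ndarray  # shape (len(expert_ids), len(model_ids)), int

    def overlap(self, expert_id: int, model_id: int) -> int:
        i = self.expert_ids.index(expert_id)
        j = self.model_ids.index(model_id)
        return int(self.counts[i, j])


def overlap_matrix(expert: LesionSet, model: LesionSet) -> OverlapMatrix:
    """Count voxels carrying each (expert label, model label) pair."""
    if expert.label_map.shape != model.label_map.shape:
        raise ValueError("expert and model label maps differ in shape")
    e = expert.label_map.labels
    m = model.label_map.labels
    eids = expert.label_map.ids()
    mids = model.label_map.ids()
    counts = np.zeros((len(eids), len(mids)), dtype=np.int64)
    both = (e > 0) & (m > 0)
    if both.any():
        epos = {lid: i for i, lid in enumerate(eids)}
        mpos = {lid: j for j, lid in enumerate(mids)}
        pairs, n = np.unique(
            np.stack([e[both], m[both]], axis=1), axis=0, return_counts=True
        )
        for (el, ml), c in zip(pairs, n):
            counts[epos[int(el)], mpos[int(ml)]] = c
    return OverlapMatrix(tuple(eids), tuple(mids), counts)


@dataclass(frozen=True)
class MergeEvent:
    side: str  # "expert" | "model"
    absorbed: tuple[int, ...]
    survivor: int


@dataclass
class CorrespondenceResult:
    merged_expert: LesionSet
    merged_model: LesionSet
    pairs: list[tuple[int, int]]
    unmatched_expert: list[int]
    unmatched_model: list[int]
    merge_log: list[MergeEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        e_seen = [e for e, _ in self.pairs]
        m_seen = [m for _, m in self.pairs]
        if len(set(e_seen)) != len(e_seen) or len(set(m_seen)) != len(m_seen):
            raise ValueError("pairs must be one-to-one")


def _merge_group(ls: LesionSet, group: list[int]) -> tuple[LesionSet, MergeEvent]:
    """Coalesce the lesions in ``group`` into the largest-volume member."""
    by_id = ls.by_id
    survivor = min(group, key=lambda i: (-by_id[i].volume_cc, i))
    absorbed = tuple(sorted(i for i in group if i != survivor))
    labels = ls.label_map.labels.copy()
    for i in absorbed:
        labels[labels == i] = survivor
    members = [by_id[i] for i in group]
    scores = [l.score for l in members if l.score is not None]
    merged = Lesion(
        id=survivor,
        volume_cc=sum(l.volume_cc for l in members),
        suv_max=max(l.suv_max for l in members),
        suv_peak=max(l.suv_peak for l in members),
        site=by_id[survivor].site,
        provenance=by_id[survivor].provenance,
        score=max(scores) if scores else None,
    )
    lesions = [merged if l.id == survivor else l for l in ls.lesions if l.id not in absorbed]
    new_ls = LesionSet(
        lesions=lesions,
        label_map=LabelMap(labels=labels, spacing=ls.label_map.spacing),
        patient_id=ls.patient_id,
    )
    return new_ls, MergeEvent(side=members[0].provenance, absorbed=absorbed, survivor=survivor)


def _fragment_groups(om: OverlapMatrix, axis: int) -> list[list[int]]:
    """Groups of >= 2 lesions along ``axis`` whose sole overlap partner is one
    common lesion on the other axis.

    axis=1: model lesions (columns) overlapping exactly one expert lesion;
    axis=0: expert lesions (rows) overlapping exactly one model lesion.
    """
    counts = om.counts
    own_ids = om.model_ids if axis == 1 else om.expert_ids
    groups: dict[int, list[int]] = {}
    for k, lid in enumerate(own_ids):
        vec = counts[:, k] if axis == 1 else counts[k, :]
        partners = np.nonzero(vec)[0]
        if len(partners) == 1:
            groups.setdefault(int(partners[0]), []).append(lid)
    return [sorted(g) for g in groups.values() if len(g) >= 2]


def merge_to_one_to_one(
    expert: LesionSet, model: LesionSet, min_overlap_voxels: int = 1
) -> CorrespondenceResult:
    """Establish the one-to-one expert/model correspondence by merging.

    Iterates the symmetric fragment-merging rule to a fixed point, then
    resolves residual many-to-many overlap by greedy assignment in
    descending shared-voxel order (ties broken by smaller (expert ID,
    model ID)).  A pair requires at least ``min_overlap_voxels`` shared
    voxels.  Merging only coalesces labels; total voxels per side are
    conserved.
    """
    merge_log: list[MergeEvent] = []
    for _ in range(1000):
        om = overlap_matrix(expert, model)
        model_groups = _fragment_groups(om, axis=1)
        expert_groups = _fragment_groups(om, axis=0)
        if not model_groups and not expert_groups:
            break
        for g in model_groups:
            model, ev = _merge_group(model, g)
            merge_log.append(ev)
        for g in expert_groups:
            expert, ev = _merge_group(expert, g)
            merge_log.append(ev)
    else:  # pragma: no cover - merging strictly decreases lesion counts
        raise RuntimeError("merge fixed point did not converge")

    om = overlap_matrix(expert, model)
    entries = [
        (int(om.counts[i, j]), om.expert_ids[i], om.model_ids[j])
        for i, j in np.argwhere(om.counts >= min_overlap_voxels)
    ]
    entries.sort(key=lambda t: (-t[0], t[1], t[2]))
    pairs: list[tuple[int, int]] = []
    used_e: set[int] = set()
    used_m: set[int] = set()
    for _, eid, mid in entries:
        if eid in used_e or mid in used_m:
            continue
        pairs.append((eid, mid))
        used_e.add(eid)
        used_m.add(mid)
    unmatched_expert = [i for i in om.expert_ids if i not in used_e]
    unmatched_model = [j for j in om.model_ids if j not in used_m]
    return CorrespondenceResult(
        merged_expert=expert,
        merged_model=model,
        pairs=pairs,
        unmatched_expert=unmatched_expert,
        unmatched_model=unmatched_model,
        merge_log=merge_log,
    )


@dataclass
class DetectionCounts:
    """TP/FP/FN counts at one score threshold, overall and per site."""

    threshold: float
    tp: int
    fp: int
    fn: int
    per_site: dict[str, tuple[int, int, int]]  # site -> (tp, fp, fn)
    tp_pairs: list[tuple[int, int]]


def classify_detections(
    result: CorrespondenceResult, score_threshold: float = 0.5
) -> DetectionCounts:
    """Classify merged lesions as TP/FP/FN at a suspiciousness threshold.

    Model lesions with score below the threshold are dropped ("benign");
    their expert partners revert to FN.  TP and FN are sited by the expert
    lesion, FP by the model lesion.  Raises if a model lesion lacks a score.
    """
    model_by_id = result.merged_model.by_id
    expert_by_id = result.merged_expert.by_id
    for l in result.merged_model.lesions:
        if l.score is None:
            raise ValueError(f"model lesion {l.id} has no probability score")

    suspicious = {i for i, l in model_by_id.items() if l.score >= score_threshold}
    tp_pairs = [(e, m) for e, m in result.pairs if m in suspicious]
    tp_e = {e for e, _ in tp_pairs}
    tp_m = {m for _, m in tp_pairs}
    fn_ids = [e for e in expert_by_id if e not in tp_e]
    fp_ids = [m for m in suspicious if m not in tp_m]

    per_site: dict[str, tuple[int, int, int]] = {}
    for site in SITES:
        tp_s = sum(1 for e, _ in tp_pairs if expert_by_id[e].site == site)
        fn_s = sum(1 for e in fn_ids if expert_by_id[e].site == site)
        fp_s = sum(1 for m in fp_ids if model_by_id[m].site == site)
        per_site[site] = (tp_s, fp_s, fn_s)
    return DetectionCounts(
        threshold=score_threshold,
        tp=len(tp_pairs),
        fp=len(fp_ids),
        fn=len(fn_ids),
        per_site=per_site,
        tp_pairs=tp_pairs,
    )
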