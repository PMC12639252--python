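"""Blood-pool-adaptive SUV-threshold lesion segmentation.

The segmenter mimics the classical front-end of automated PET reading
systems: candidate foci are local SUV maxima whose SUVpeak exceeds the
mean blood-pool uptake (SUVBP) by more than a configurable number of
standard deviations (default 2), and each focus is contoured as the
connected region above a fixed fraction (default 42 %) of its local
SUVmax.  Segmented components smaller than a minimum volume (default
0.5 cc) are discarded.

"Local SUVmax" is resolved by a fixed point: grow the component at 42 %
of the seed value, update the maximum over the grown region, re-grow at
42 % of the new maximum, and repeat until stable, so the final threshold
is always 42 % of the true maximum of the emitted region regardless of
which interior focus seeded it.

The downstream malignancy classifier of such systems is a trained neural
network and is deliberately not part of this module; probability scores
enter the pipeline via the synthetic reader or external lesion tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelMap, LesionSet, SuvVolume, extract_lesions, suv_peak_map

__all__ = [
    "BloodPoolStats",
    "SegmenterConfig",
    "blood_pool_stats",
    "detect_foci",
    "segment_focus",
    "segment_volume",
]


@dataclass(frozen=True)
class BloodPoolStats:
    """Mean and sample SD of SUV over the blood-pool reference region."""

    mean_bp: float
    sd_bp: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("blood-pool statistics need at least 2 voxels")
        if self.sd_bp < 0:
            raise ValueError("sd must be non-negative")

    def detection_threshold(self, sd_multiplier: float) -> float:
        return self.mean_bp + sd_multiplier * self.sd_bp


@dataclass(frozen=True)
class SegmenterConfig:
    """Tunable parameters of the rule-based segmenter.

    threshold_fraction
        Fraction of the local SUVmax used as the contouring isolevel.
    detection_sd_multiplier
        How many blood-pool SDs above the blood-pool mean a candidate's
        SUVpeak must lie to be considered a focus.
    min_volume_cc
        Components strictly smaller than this are excluded; exactly this
        volume is retained.
    peak_sphere_cc
        Volume of the SUVpeak averaging sphere.
    connectivity
        Voxel neighbourhood: 6 (faces), 18 (+edges) or 26 (+corners).
    """

    threshold_fraction: float = 0.42
    detection_sd_multiplier: float = 2.0
    min_volume_cc: float = 0.5
    peak_sphere_cc: float = 1.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.min_volume_cc < 0:
            raise ValueError("min_volume_cc must be >= 0")
        if self.peak_sphere_cc <= 0:
            raise ValueError("peak_sphere_cc must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


_CONN_TO_STRUCT_RANK = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _CONN_TO_STRUCT_RANK[connectivity])


def blood_pool_stats(volume: SuvVolume, bp_mask: LabelMap) -> BloodPoolStats:
    """Mean and sample (n-1) standard deviation of SUV over a mask."""
    if bp_mask.shape != volume.shape:
        raise ValueError("blood-pool mask shape mismatch")
    vals = volume.values[bp_mask.labels > 0]
    if vals.size < 2:
        raise ValueError(f"blood-pool mask has {vals.size} voxels; need at least 2")
    return BloodPoolStats(
        mean_bp=float(vals.mean()),
        sd_bp=float(vals.std(ddof=1)),
        n_voxels=int(vals.size),
    )


def detect_foci(
    volume: SuvVolume, bp: BloodPoolStats, cfg: SegmenterConfig = SegmenterConfig()
) -> list[tuple[int, int, int]]:
    """Candidate foci: local SUV maxima with SUVpeak above the adaptive threshold.

    A voxel is a local maximum when its SUV is >= all neighbours under the
    configured connectivity.  Candidates are returned sorted by descending
    SUVpeak.
    """
    struct = _structure(cfg.connectivity)
    footprint = struct.copy()
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(
        volume.values, footprint=footprint, mode="constant", cval=-np.inf
    )
    is_local_max = volume.values >= neigh_max
    peak = suv_peak_map(volume, cfg.peak_sphere_cc)
    thr = bp.detection_threshold(cfg.detection_sd_multiplier)
    cand = is_local_max & (peak > thr)
    idx = np.argwhere(cand)
    order = np.argsort(-peak[cand], kind="stable")
    return [tuple(int(c) for c in idx[o]) for o in order]


def segment_focus(
    volume: SuvVolume, focus: tuple[int, int, int], cfg: SegmenterConfig = SegmenterConfig()
) -> np.ndarray:
    """Contour one focus at ``threshold_fraction`` of its local SUVmax.

    Returns a boolean mask: the connected component above the fixed-point
    threshold that contains the voxel attaining the local maximum.  The
    seed starts at the focus; if the iteration discovers a hotter maximum
    reachable above the running threshold, the component is re-seeded at
    that maximum, so the emitted region always contains its own SUVmax.
    """
    focus = tuple(int(c) for c in focus)
    if any(c < 0 or c >= s for c, s in zip(focus, volume.shape)):
        raise ValueError(f"focus {focus} outside grid")
    struct = _structure(cfg.connectivity)
    vals = volume.values
    seed = focus
    local_max = float(vals[focus])
    for _ in range(100):  # fixed point reached in a handful of iterations
        thr = cfg.threshold_fraction * local_max
        above = vals >= thr
        labels, _ = ndimage.label(above, structure=struct)
        comp = labels == labels[seed]
        comp_vals = vals[comp]
        new_max = float(comp_vals.max())
        if new_max <= local_max:
            return comp
        local_max = new_max
        flat = np.argmax(np.where(comp, vals, -np.inf))
        seed = tuple(int(c) for c in np.unravel_index(flat, vals.shape))
    raise RuntimeError("segment_focus fixed point did not converge")


def segment_volume(
    volume: SuvVolume,
    bp_mask: LabelMap,
    site_map: LabelMap | None = None,
    cfg: SegmenterConfig = SegmenterConfig(),
    patient_id: str = "p0",
) -> LesionSet:
    """Full rule-based segmentation of one volume.

    Detects foci, contours each, enforces voxel-disjointness (components
    are taken in descending SUVmax order; a later component overlapping an
    already-kept one is dropped — identical duplicates from multiple seeds
    inside one lesion fall out here), applies the minimum-volume filter
    (strictly smaller excluded), and assigns consecutive IDs by descending
    SUVmax.
    """
    bp = blood_pool_stats(volume, bp_mask)
    foci = detect_foci(volume, bp, cfg)
    vox_cc = volume.voxel_volume_cc

    masks: list[tuple[float, np.ndarray]] = []
    for focus in foci:
        comp = segment_focus(volume, focus, cfg)
        masks.append((float(volume.values[comp].max()), comp))
    masks.sort(key=lambda t: -t[0])

    labels = np.zeros(volume.shape, dtype=np.int32)
    occupied = np.zeros(volume.shape, dtype=bool)
    next_id = 1
    for suv_max, comp in masks:
        if (comp & occupied).any():
            continue
        if comp.sum() * vox_cc < cfg.min_volume_cc:
            occupied |= comp  # still claims its voxels; just not reported
            continue
        labels[comp] = next_id
        occupied |= comp
        next_id += 1

    label_map = LabelMap(labels=labels, spacing=volume.spacing)
    return extract_lesions(
        label_map,
        volume,
        site_map=site_map,
        provenance="model",
        patient_id=patient_id,
        peak_sphere_cc=cfg.peak_sphere_cc,
    )
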