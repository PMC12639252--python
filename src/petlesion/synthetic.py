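"""Synthetic PET phantoms and a simulated automated reader.

Clinical FDG-PET cohorts are confidential, so every pipeline stage here is
exercised on synthetic data with known ground truth.  Two generators are
provided:

* :func:`generate_phantom` paints a 3D SUV phantom — organ compartments
  with site-specific uptake, a blood-pool reference region, and hard
  spherical lesions of known volume/site/SUVmax — then applies an
  isotropic Gaussian point-spread blur (scanner resolution) and additive
  Gaussian noise.  The expert reference label map is the crisp pre-blur
  insert, mimicking CT-refined expert contours, while the segmenter sees
  the blurred volume, mimicking PET-threshold contours.

* :func:`simulate_model_output` emulates the behaviours automated readers
  exhibit against expert references: per-site detection probability,
  fragmentation of single lesions into several components, boundary
  jitter, Poisson false positives with log-normal volumes, and
  malignancy-probability scores drawn from Beta distributions (one for
  true lesions, one for false positives).

:func:`expected_reader_metrics` gives the closed-form precision/recall
curve implied by a reader specification (Beta tail probabilities and the
Poisson false-positive rate); it is the analytic oracle for
parameter-recovery tests of the measured pipeline.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import (
    SITES,
    SITE_TO_CODE,
    LabelMap,
    LesionSet,
    SuvVolume,
    extract_lesions,
    voxel_volume_cc,
)
from .correspondence import CorrespondenceResult, merge_to_one_to_one

__all__ = [
    "OrganSpec",
    "LesionSpec",
    "PhantomSpec",
    "ReaderSpec",
    "Phantom",
    "generate_phantom",
    "simulate_model_output",
    "expected_reader_metrics",
    "sample_cohort_specs",
    "simulate_detection_cohort",
    "regime_presets",
    "COHORT_SITE_MIX",
]

#: Site mix of a typical metastatic-melanoma cohort (fractions over
#: lymph_node, lung, liver, bone, other).
COHORT_SITE_MIX: Mapping[str, float] = {
    "lymph_node": 0.330,
    "lung": 0.185,
    "liver": 0.128,
    "bone": 0.121,
    "other": 0.236,
}


@dataclass(frozen=True)
class OrganSpec:
    """An axis-aligned box compartment with Gaussian SUV texture.

    ``center`` and ``half_size`` are fractions of the grid extent.
    """

    center: tuple[float, float, float]
    half_size: tuple[float, float, float]
    mean_suv: float
    sd_suv: float


@dataclass(frozen=True)
class LesionSpec:
    """A hard spherical lesion insert: voxel-index center, radius in mm."""

    center: tuple[int, int, int]
    radius_mm: float
    suv_max: float
    site: str

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")


def _default_organs() -> dict[str, OrganSpec]:
    # Abdomen/thorax cartoon on a unit cube: lungs top, liver mid-right,
    # bone (spine) central column, nodal stations mid-left.  Organ uptake is
    # kept below the blood-pool detection band: the rule segmenter carries
    # no organ-exclusion logic, so physiological-uptake false positives are
    # emulated through the reader's fp_rate instead of hot organs.
    return {
        "lung": OrganSpec((0.5, 0.28, 0.72), (0.38, 0.20, 0.20), 0.4, 0.05),
        "liver": OrganSpec((0.70, 0.72, 0.45), (0.20, 0.20, 0.18), 1.6, 0.15),
        "bone": OrganSpec((0.5, 0.52, 0.14), (0.36, 0.34, 0.10), 1.0, 0.10),
        "lymph_node": OrganSpec((0.24, 0.72, 0.45), (0.16, 0.20, 0.18), 0.9, 0.08),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic patient volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    background_mean: float = 0.8
    background_sd: float = 0.05
    organs: Mapping[str, OrganSpec] = field(default_factory=_default_organs)
    blood_pool_center: tuple[float, float, float] = (0.5, 0.5, 0.55)
    blood_pool_radius_frac: float = 0.045
    blood_pool_half_height_frac: float = 0.28
    blood_pool_mean: float = 1.8
    blood_pool_sd: float = 0.15
    lesions: tuple[LesionSpec, ...] = ()
    psf_sigma_mm: float = 3.0
    noise_sd: float = 0.02
    seed: int = 0


@dataclass
class Phantom:
    """Output bundle of :func:`generate_phantom`."""

    volume: SuvVolume
    expert_labels: LabelMap
    site_map: LabelMap
    blood_pool_mask: LabelMap
    truth: pd.DataFrame  # lesion_id, site, volume_cc, suv_max, radius_mm
    patient_id: str = "p0"

    def expert_lesion_set(self) -> LesionSet:
        return extract_lesions(
            self.expert_labels,
            self.volume,
            site_map=self.site_map,
            provenance="expert",
            patient_id=self.patient_id,
        )


def _sphere_mask(shape: Sequence[int], spacing: Sequence[float],
                 center: Sequence[int], radius_mm: float) -> np.ndarray:
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    lo = [max(0, c - h) for c, h in zip(center, half)]
    hi = [min(n, c + h + 1) for c, h, n in zip(center, half, shape)]
    mask = np.zeros(tuple(shape), dtype=bool)
    ax = [np.arange(l, h) for l, h in zip(lo, hi)]
    if any(a.size == 0 for a in ax):
        return mask
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    d2 = (
        ((ii - center[0]) * spacing[0]) ** 2
        + ((jj - center[1]) * spacing[1]) ** 2
        + ((kk - center[2]) * spacing[2]) ** 2
    )
    mask[ii, jj, kk] = d2 <= radius_mm**2
    return mask


def generate_phantom(spec: PhantomSpec, patient_id: str = "p0") -> Phantom:
    """Render a PhantomSpec into a blurred, noisy SUV volume with truth.

    Raises if two lesion inserts overlap (keeps the truth unambiguous).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = tuple(spec.spacing)
    ext = np.asarray(shape)

    suv = rng.normal(spec.background_mean, spec.background_sd, size=shape)
    site_map = np.full(shape, SITE_TO_CODE["other"], dtype=np.int32)

    idx = np.indices(shape)
    for site, organ in spec.organs.items():
        c = np.asarray(organ.center) * ext
        h = np.asarray(organ.half_size) * ext
        inside = np.all(
            [np.abs(idx[a] - c[a]) <= h[a] for a in range(3)], axis=0
        )
        suv[inside] = rng.normal(organ.mean_suv, organ.sd_suv, size=int(inside.sum()))
        site_map[inside] = SITE_TO_CODE[site]

    # Blood pool: vertical cylinder (descending-aorta-like reference region).
    c = np.asarray(spec.blood_pool_center) * ext
    r_vox = spec.blood_pool_radius_frac * max(shape)
    hh = spec.blood_pool_half_height_frac * ext[2]
    d2 = (idx[0] - c[0]) ** 2 + (idx[1] - c[1]) ** 2
    bp = (d2 <= r_vox**2) & (np.abs(idx[2] - c[2]) <= hh)
    suv[bp] = rng.normal(spec.blood_pool_mean, spec.blood_pool_sd, size=int(bp.sum()))

    labels = np.zeros(shape, dtype=np.int32)
    truth_rows = []
    vox_cc = voxel_volume_cc(spacing)
    for i, les in enumerate(spec.lesions, start=1):
        mask = _sphere_mask(shape, spacing, les.center, les.radius_mm)
        if not mask.any():
            raise ValueError(f"lesion {i} lies outside the grid")
        if (labels[mask] != 0).any():
            raise ValueError(f"lesion {i} overlaps a previous insert")
        labels[mask] = i
        suv[mask] = les.suv_max
        site_map[mask] = SITE_TO_CODE[les.site]
        truth_rows.append(
            {
                "lesion_id": i,
                "site": les.site,
                "volume_cc": float(mask.sum()) * vox_cc,
                "suv_max": les.suv_max,
                "radius_mm": les.radius_mm,
            }
        )

    sigma_vox = [spec.psf_sigma_mm / s for s in spacing]
    blurred = ndimage.gaussian_filter(suv, sigma=sigma_vox)
    if spec.noise_sd > 0:
        blurred = blurred + rng.normal(0.0, spec.noise_sd, size=shape)
    blurred = np.clip(blurred, 0.0, None)

    return Phantom(
        volume=SuvVolume(values=blurred.astype(np.float32), spacing=spacing),
        expert_labels=LabelMap(labels=labels, spacing=spacing),
        site_map=LabelMap(labels=site_map, spacing=spacing),
        blood_pool_mask=LabelMap(labels=bp.astype(np.int32), spacing=spacing),
        truth=pd.DataFrame(
            truth_rows,
            columns=["lesion_id", "site", "volume_cc", "suv_max", "radius_mm"],
        ),
        patient_id=patient_id,
    )


# ---------------------------------------------------------------------------
# Simulated reader


def _per_site(value: "float | Mapping[str, float]") -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [s for s in SITES if s not in value]
        if missing:
            raise ValueError(f"missing sites {missing}")
        return dict(value)
    return {s: float(value) for s in SITES}


@dataclass(frozen=True)
class ReaderSpec:
    """Statistical description of a simulated automated reader.

    detection_prob
        Probability a true lesion is segmented at all, scalar or per site.
        Defaults qualitatively follow reported per-site recall orderings
        (liver and bone high, lung low); illustrative, not fitted.
    split_prob / n_fragments
        Probability a detected lesion is emitted as several connected
        fragments, and how many.
    boundary_jitter_mm
        Magnitude of random dilation/erosion of detected contours.
    fp_rate
        Mean false-positive candidates per patient (Poisson).  Most draw
        benign scores under the default Beta(2, 8), so the suspicious FP
        load is roughly fp_rate times the Beta upper tail at the working
        threshold.
    fp_volume_lognorm
        (mean, sigma) of log volume in cc for false positives.
    score_true_beta / score_false_beta
        Beta(a, b) parameters of the malignancy score for detected true
        lesions and for false positives.
    """

    detection_prob: "float | Mapping[str, float]" = field(
        default_factory=lambda: {
            "lymph_node": 0.71,
            "lung": 0.58,
            "liver": 0.82,
            "bone": 0.75,
            "other": 0.65,
        }
    )
    split_prob: float = 0.15
    n_fragments: int = 2
    merge_prob: float = 0.0
    boundary_jitter_mm: float = 1.0
    fp_rate: float = 43.0
    fp_volume_lognorm: tuple[float, float] = (np.log(0.7), 0.8)
    score_true_beta: tuple[float, float] = (8.0, 2.0)
    score_false_beta: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = _per_site(self.detection_prob)
        if any(not 0 <= p <= 1 for p in probs.values()):
            raise ValueError("detection probabilities must lie in [0, 1]")
        if not 0 <= self.split_prob <= 1:
            raise ValueError("split_prob must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if self.n_fragments < 2:
            raise ValueError("n_fragments must be >= 2")

    def detection_prob_for(self, site: str) -> float:
        return _per_site(self.detection_prob)[site]


def _split_mask(mask: np.ndarray, n: int) -> list[np.ndarray]:
    """Split a connected mask into up to ``n`` contiguous slabs along its
    longest axis; slabs of a convex-ish region stay connected."""
    idx = np.argwhere(mask)
    extents = idx.max(axis=0) - idx.min(axis=0)
    axis = int(np.argmax(extents))
    coords = idx[:, axis]
    cuts = np.quantile(coords, np.linspace(0, 1, n + 1)[1:-1])
    pieces = []
    assign = np.searchsorted(cuts, coords, side="right")
    for k in range(n):
        sel = idx[assign == k]
        if len(sel) == 0:
            continue
        piece = np.zeros_like(mask)
        piece[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        pieces.append(piece)
    return pieces if len(pieces) >= 2 else [mask]


def _jitter_mask(mask: np.ndarray, spacing: Sequence[float],
                 jitter_mm: float, rng: np.random.Generator) -> np.ndarray:
    if jitter_mm <= 0:
        return mask
    it = max(1, int(round(jitter_mm / min(spacing))))
    if rng.random() < 0.5:
        out = ndimage.binary_erosion(mask, iterations=it)
        return out if out.any() else mask
    return ndimage.binary_dilation(mask, iterations=it)


def simulate_model_output(
    truth: LesionSet,
    site_map: LabelMap,
    reader: ReaderSpec,
    volume: SuvVolume,
    seed: int | None = None,
) -> LesionSet:
    """Emulate an automated reader on a phantom's ground truth.

    Per true lesion: Bernoulli(detection_prob[site]) keep/drop; kept
    lesions are either split into connected fragments or boundary-jittered.
    Poisson(fp_rate) false positives are placed as spheres in unoccupied
    background with log-normal volumes.  Scores come from the true/false
    Beta distributions.  Deterministic given the seed (``reader.seed``
    unless overridden).
    """
    rng = np.random.default_rng(reader.seed if seed is None else seed)
    shape = truth.label_map.shape
    spacing = truth.label_map.spacing
    probs = _per_site(reader.detection_prob)
    a_t, b_t = reader.score_true_beta
    a_f, b_f = reader.score_false_beta

    labels = np.zeros(shape, dtype=np.int32)
    scores: dict[int, float] = {}
    next_id = 1
    for les in truth.lesions:
        mask = truth.label_map.labels == les.id
        if rng.random() >= probs[les.site]:
            continue
        if rng.random() < reader.split_prob:
            pieces = _split_mask(mask, reader.n_fragments)
        else:
            pieces = [_jitter_mask(mask, spacing, reader.boundary_jitter_mm, rng)]
        for piece in pieces:
            piece = piece & (labels == 0)
            if not piece.any():
                continue
            labels[piece] = next_id
            scores[next_id] = float(rng.beta(a_t, b_t))
            next_id += 1

    n_fp = int(rng.poisson(reader.fp_rate))
    occupied = (labels > 0) | (truth.label_map.labels > 0)
    mu, sig = reader.fp_volume_lognorm
    for _ in range(n_fp):
        vol_cc = float(np.exp(rng.normal(mu, sig)))
        radius_mm = (3.0 * vol_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        for _try in range(50):
            center = tuple(int(rng.integers(0, s)) for s in shape)
            mask = _sphere_mask(shape, spacing, center, radius_mm)
            if mask.any() and not (mask & occupied).any():
                labels[mask] = next_id
                scores[next_id] = float(rng.beta(a_f, b_f))
                occupied |= mask
                next_id += 1
                break

    label_map = LabelMap(labels=labels, spacing=spacing)
    return extract_lesions(
        label_map,
        volume,
        site_map=site_map,
        provenance="model",
        scores=scores,
        patient_id=truth.patient_id,
    )


# ---------------------------------------------------------------------------
# Closed-form expectations and table-level cohorts


def expected_reader_metrics(
    reader: ReaderSpec,
    site_counts: Mapping[str, int],
    n_patients: int,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Analytic precision/recall curve implied by a ReaderSpec.

    recall(t) = Σ_s n_s·p_s·P(score_true ≥ t) / Σ_s n_s;
    E[TP](t) uses the same Beta tail, E[FP](t) = n_patients·fp_rate·
    P(score_false ≥ t); precision(t) = E[TP]/(E[TP]+E[FP]).  Percentages.
    """
    a_t, b_t = reader.score_true_beta
    a_f, b_f = reader.score_false_beta
    probs = _per_site(reader.detection_prob)
    n_total = sum(site_counts.values())
    rows = []
    for t in thresholds:
        sf_t = float(stats.beta.sf(t, a_t, b_t)) if t > 0 else 1.0
        sf_f = float(stats.beta.sf(t, a_f, b_f)) if t > 0 else 1.0
        etp = sum(site_counts[s] * probs[s] * sf_t for s in site_counts)
        efp = n_patients * reader.fp_rate * sf_f
        rows.append(
            {
                "threshold": t,
                "expected_tp": etp,
                "expected_fp": efp,
                "recall": 100.0 * etp / n_total if n_total else np.nan,
                "precision": 100.0 * etp / (etp + efp) if etp + efp > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def sample_cohort_specs(
    n_patients: int = 30,
    seed: int = 0,
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> list[PhantomSpec]:
    """Sample a cohort of PhantomSpecs emulating a realistic case mix.

    Lesion counts follow a shifted negative binomial (median ≈ 3, long
    right tail); sites follow the cohort site mix; radii are log-normal
    (median ≈ 9 mm); SUVmax uniform in [4, 12].  Lesions are placed inside
    their site's organ compartment by rejection sampling, non-overlapping.
    """
    rng = np.random.default_rng(seed)
    organs = _default_organs()
    specs = []
    site_names = list(COHORT_SITE_MIX)
    site_p = np.array([COHORT_SITE_MIX[s] for s in site_names])
    site_p = site_p / site_p.sum()
    for p in range(n_patients):
        n_lesions = 1 + int(rng.negative_binomial(1.6, 0.4))
        lesions: list[LesionSpec] = []
        placed: list[tuple[np.ndarray, float]] = []
        ext = np.asarray(shape)
        for _ in range(n_lesions):
            site = str(rng.choice(site_names, p=site_p))
            radius = float(np.clip(np.exp(rng.normal(np.log(9.0), 0.35)), 5.0, 20.0))
            for _try in range(200):
                if site in organs:
                    o = organs[site]
                    lo = (np.asarray(o.center) - np.asarray(o.half_size)) * ext
                    hi = (np.asarray(o.center) + np.asarray(o.half_size)) * ext
                else:
                    lo, hi = 0.12 * ext, 0.88 * ext
                center = np.array(
                    [int(rng.uniform(l, h)) for l, h in zip(lo, hi)]
                )
                center = np.clip(center, 3, ext - 4)
                min_gap = radius + 2.0 * min(spacing)
                ok = all(
                    np.linalg.norm((center - c) * np.asarray(spacing)) > min_gap + r
                    for c, r in placed
                )
                if ok:
                    placed.append((center, radius))
                    lesions.append(
                        LesionSpec(
                            center=tuple(int(c) for c in center),
                            radius_mm=radius,
                            suv_max=float(rng.uniform(4.0, 12.0)),
                            site=site,
                        )
                    )
                    break
        specs.append(
            PhantomSpec(
                shape=shape,
                spacing=spacing,
                lesions=tuple(lesions),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def simulate_detection_cohort(
    reader: ReaderSpec,
    n_patients: int,
    n_lesions: int,
    seed: int = 0,
    grid: int = 40,
    spacing: float = 3.0,
) -> list[CorrespondenceResult]:
    """Table-level cohort for score-threshold studies.

    Lesions are represented as single voxels on a coarse grid (degenerate
    geometry): a detected lesion's model voxel coincides with its expert
    voxel, false positives occupy free voxels.  This exercises the real
    correspondence/classification chain at cohort scale without rendering
    images, so the measured precision–recall curve can be compared against
    :func:`expected_reader_metrics` closed forms.
    """
    rng = np.random.default_rng(seed)
    probs = _per_site(reader.detection_prob)
    a_t, b_t = reader.score_true_beta
    a_f, b_f = reader.score_false_beta
    site_names = list(COHORT_SITE_MIX)
    site_p = np.array([COHORT_SITE_MIX[s] for s in site_names])
    site_p = site_p / site_p.sum()
    base = n_lesions // n_patients
    per_patient = [base + (1 if i < n_lesions % n_patients else 0) for i in range(n_patients)]
    shape = (grid, grid, grid)
    sp = (spacing, spacing, spacing)

    results = []
    for p, n_true in enumerate(per_patient):
        n_fp = int(rng.poisson(reader.fp_rate))
        total = n_true + n_fp
        if total > grid**3:
            raise ValueError("grid too small for the requested lesion load")
        flat = rng.choice(grid**3, size=total, replace=False)
        coords = np.stack(np.unravel_index(flat, shape), axis=1)
        elabels = np.zeros(shape, dtype=np.int32)
        mlabels = np.zeros(shape, dtype=np.int32)
        suv = np.full(shape, 1.0, dtype=np.float32)
        sites = rng.choice(len(site_names), size=n_true, p=site_p)
        site_codes = np.zeros(shape, dtype=np.int32)
        escores: dict[int, float] = {}
        mscores: dict[int, float] = {}
        mid = 1
        for i in range(n_true):
            c = coords[i]
            elabels[c[0], c[1], c[2]] = i + 1
            site_codes[c[0], c[1], c[2]] = SITE_TO_CODE[site_names[sites[i]]]
            if rng.random() < probs[site_names[sites[i]]]:
                mlabels[c[0], c[1], c[2]] = mid
                mscores[mid] = float(rng.beta(a_t, b_t))
                mid += 1
        for i in range(n_true, total):
            c = coords[i]
            mlabels[c[0], c[1], c[2]] = mid
            mscores[mid] = float(rng.beta(a_f, b_f))
            mid += 1
        vol = SuvVolume(values=suv, spacing=sp)
        smap = LabelMap(labels=site_codes, spacing=sp)
        expert = extract_lesions(
            LabelMap(labels=elabels, spacing=sp), vol, site_map=smap,
            provenance="expert", patient_id=f"p{p}",
        )
        model = extract_lesions(
            LabelMap(labels=mlabels, spacing=sp), vol, site_map=smap,
            provenance="model", scores=mscores, patient_id=f"p{p}",
        )
        results.append(merge_to_one_to_one(expert, model))
    return results


def regime_presets() -> dict[str, ReaderSpec]:
    """Named reader regimes spanning the qualitative failure modes seen in
    practice: systematic undersegmentation, a well-matched reader, and a
    false-positive-dominated reader; plus an ideal "identity" reader that
    reproduces the reference exactly (all lesions detected, untouched,
    scored suspicious) for end-to-end sanity checks."""
    return {
        "identity": ReaderSpec(
            detection_prob=1.0, split_prob=0.0, boundary_jitter_mm=0.0,
            fp_rate=0.0, score_true_beta=(1000.0, 1.0), seed=10,
        ),
        "undersegmentation": ReaderSpec(
            detection_prob=0.55, split_prob=0.05, boundary_jitter_mm=3.0,
            fp_rate=0.5, seed=11,
        ),
        "good_match": ReaderSpec(
            detection_prob=0.95, split_prob=0.0, boundary_jitter_mm=0.0,
            fp_rate=0.2, seed=12,
        ),
        "fp_dominated": ReaderSpec(
            detection_prob=0.8, split_prob=0.1, boundary_jitter_mm=1.0,
            fp_rate=12.0, score_false_beta=(5.0, 3.0), seed=13,
        ),
    }
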