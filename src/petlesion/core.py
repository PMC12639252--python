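"""Core data model and I/O for SUV volumes, label maps and lesion tables.

Quantitative FDG-PET expresses voxel intensity as the standardized uptake
value (SUV), a dimensionless, body-weight-normalized measure of tracer
uptake.  This module provides the in-memory containers used throughout the
package — :class:`SuvVolume` for the imaging substrate, :class:`LabelMap`
for 3D instance segmentations (one integer ID per lesion, 0 = background),
and :class:`Lesion`/:class:`LesionSet` for per-focus features — together
with NIfTI-1 readers/writers (via nibabel) and CSV lesion tables (via
pandas).

All grids are index-addressed; the only geometric information carried is
the per-axis voxel spacing in millimetres, from which volumes in cubic
centimetres are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SITES",
    "SuvVolume",
    "LabelMap",
    "Lesion",
    "LesionSet",
    "FormatError",
    "read_suv_volume",
    "write_suv_volume",
    "read_label_map",
    "write_label_map",
    "voxel_volume_cc",
    "compute_suv_peak",
    "extract_lesions",
    "lesion_table",
    "read_lesion_table",
    "write_lesion_table",
]

#: Anatomical site categories used for stratified reporting.
SITES = ("lymph_node", "lung", "liver", "bone", "other")

#: Integer codes used in site maps (0 is "unassigned" and falls back to "other").
SITE_CODES: Mapping[int, str] = {1: "lymph_node", 2: "lung", 3: "liver", 4: "bone", 5: "other"}
SITE_TO_CODE: Mapping[str, int] = {v: k for k, v in SITE_CODES.items()}


class FormatError(ValueError):
    """Raised when an on-disk volume violates the expected NIfTI contract."""


def voxel_volume_cc(spacing: Sequence[float]) -> float:
    """Volume of one voxel in cubic centimetres for a spacing triple in mm.

    1 cc = 1000 mm^3, so a (10, 10, 10) mm voxel is exactly 1 cc.
    """
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive mm values, got {spacing}")
    return spacing[0] * spacing[1] * spacing[2] / 1000.0


@dataclass(frozen=True)
class SuvVolume:
    """A 3D scalar field of SUV values with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float32)
        if values.ndim != 3:
            raise ValueError(f"SUV volume must be 3D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV values must be finite")
        if np.any(values < 0):
            raise ValueError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive mm values, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        return voxel_volume_cc(self.spacing)


@dataclass(frozen=True)
class LabelMap:
    """A 3D non-negative integer instance map; label 0 is background."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"label map must be 3D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise ValueError("label map must hold integers")
            labels = rounded.astype(np.int32)
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive mm values, got {spacing}")
        object.__setattr__(self, "labels", np.ascontiguousarray(labels, dtype=np.int32))
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_cc(self) -> float:
        return voxel_volume_cc(self.spacing)

    def ids(self) -> list[int]:
        """Sorted nonzero label IDs present in the map."""
        u = np.unique(self.labels)
        return [int(i) for i in u if i != 0]


@dataclass(frozen=True)
class Lesion:
    """One segmented focus with its scalar features.

    ``score`` is the model's probability that the focus is malignant
    ("suspicious" at score >= threshold); expert lesions carry no score.
    """

    id: int
    volume_cc: float
    suv_max: float
    suv_peak: float
    site: str
    provenance: str  # "expert" | "model"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError("lesion id must be positive")
        if self.volume_cc <= 0:
            raise ValueError("lesion volume must be positive")
        if self.suv_peak > self.suv_max + 1e-6:
            raise ValueError("suv_peak cannot exceed suv_max")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.provenance not in ("expert", "model"):
            raise ValueError(f"provenance must be 'expert' or 'model', got {self.provenance!r}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class LesionSet:
    """A collection of lesions for one patient, indexed by a label map."""

    lesions: list[Lesion]
    label_map: LabelMap
    patient_id: str = "p0"

    def __post_init__(self) -> None:
        map_ids = set(self.label_map.ids())
        set_ids = {l.id for l in self.lesions}
        if map_ids != set_ids:
            raise ValueError(
                f"label map IDs {sorted(map_ids)} do not match lesion IDs {sorted(set_ids)}"
            )
        if len(set_ids) != len(self.lesions):
            raise ValueError("duplicate lesion IDs")

    def __len__(self) -> int:
        return len(self.lesions)

    def __getitem__(self, lesion_id: int) -> Lesion:
        for l in self.lesions:
            if l.id == lesion_id:
                return l
        raise KeyError(lesion_id)

    @property
    def by_id(self) -> dict[int, Lesion]:
        return {l.id: l for l in self.lesions}

    def total_volume_cc(self) -> float:
        return float(sum(l.volume_cc for l in self.lesions))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _check_header(img: nib.Nifti1Image, path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got dim={data.ndim} (header field 'dim')")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel size in header field 'pixdim': {zooms}")
    return data, tuple(float(z) for z in zooms)


def read_suv_volume(path: str | Path) -> SuvVolume:
    """Read a 3D SUV volume from a NIfTI-1 file, spacing from the header pixdim."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, spacing = _check_header(nib.load(str(path)), path)
    return SuvVolume(values=data.astype(np.float32), spacing=spacing)


def write_suv_volume(volume: SuvVolume, path: str | Path) -> None:
    """Write a SuvVolume as 32-bit float NIfTI-1; spacing goes to pixdim."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_label_map(path: str | Path) -> LabelMap:
    """Read an integer label map from a NIfTI-1 file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, spacing = _check_header(nib.load(str(path)), path)
    return LabelMap(labels=np.rint(data).astype(np.int32), spacing=spacing)


def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    affine = np.diag(list(label_map.spacing) + [1.0])
    img = nib.Nifti1Image(label_map.labels.astype(np.int32), affine)
    img.header.set_zooms(label_map.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Feature extraction


def _sphere_offsets(spacing: Sequence[float], sphere_cc: float) -> np.ndarray:
    """Integer voxel offsets whose centers lie within a sphere of given volume.

    The sphere radius follows from V = 4/3 pi r^3 with V in mm^3.
    """
    radius_mm = (3.0 * sphere_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) for h in half]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    d2 = (ii * spacing[0]) ** 2 + (jj * spacing[1]) ** 2 + (kk * spacing[2]) ** 2
    inside = d2 <= radius_mm**2
    return np.stack([ii[inside], jj[inside], kk[inside]], axis=1)


def compute_suv_peak(
    volume: SuvVolume, center: Sequence[int], peak_sphere_cc: float = 1.0
) -> float:
    """Mean SUV within a sphere of ``peak_sphere_cc`` centred on a voxel.

    This is the conventional SUVpeak: a small-sphere (by default 1 cc)
    average placed at the hottest location, robust to single-voxel noise.
    The sphere is clipped to the grid near edges.
    """
    center = tuple(int(c) for c in center)
    shape = volume.shape
    if any(c < 0 or c >= s for c, s in zip(center, shape)):
        raise ValueError(f"center {center} outside grid of shape {shape}")
    offsets = _sphere_offsets(volume.spacing, peak_sphere_cc)
    pts = offsets + np.asarray(center)
    ok = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
    pts = pts[ok]
    return float(volume.values[pts[:, 0], pts[:, 1], pts[:, 2]].mean())


def suv_peak_map(volume: SuvVolume, peak_sphere_cc: float = 1.0) -> np.ndarray:
    """SUVpeak evaluated at every voxel (sphere mean, clipped at edges).

    Computed by FFT convolution of the volume and of an all-ones grid with
    the sphere kernel; the ratio is exactly the clipped-sphere mean.
    """
    from scipy.signal import fftconvolve

    offsets = _sphere_offsets(volume.spacing, peak_sphere_cc)
    half = offsets.max(axis=0)
    kshape = 2 * half + 1
    kernel = np.zeros(kshape)
    kernel[offsets[:, 0] + half[0], offsets[:, 1] + half[1], offsets[:, 2] + half[2]] = 1.0
    num = fftconvolve(volume.values.astype(np.float64), kernel, mode="same")
    den = fftconvolve(np.ones(volume.shape), kernel, mode="same")
    return num / den


def _majority_site(site_codes: np.ndarray) -> str:
    """Majority site over a lesion's voxels; ties go to the lexicographically
    first site name; code 0 (unassigned) maps to 'other'."""
    names = [SITE_CODES.get(int(c), "other") if c != 0 else "other" for c in site_codes]
    counts: dict[str, int] = {}
    for n in names:
        counts[n] = counts.get(n, 0) + 1
    return min(counts, key=lambda name: (-counts[name], name))


def extract_lesions(
    label_map: LabelMap,
    volume: SuvVolume,
    site_map: LabelMap | None = None,
    provenance: str = "expert",
    scores: Mapping[int, float] | None = None,
    patient_id: str = "p0",
    peak_sphere_cc: float = 1.0,
) -> LesionSet:
    """Build a LesionSet from a label map: per-lesion volume, SUVmax, SUVpeak, site.

    ``volume_cc`` is voxel count times the voxel volume; ``suv_peak`` is the
    sphere mean at the lesion's hottest voxel; ``site`` is the majority site
    code over the lesion's voxels (ties to the alphabetically first name).
    An empty label map yields an empty LesionSet.
    """
    if label_map.shape != volume.shape:
        raise ValueError(f"label map shape {label_map.shape} != volume shape {volume.shape}")
    if site_map is not None and site_map.shape != volume.shape:
        raise ValueError("site map shape mismatch")
    vox_cc = label_map.voxel_volume_cc
    lesions: list[Lesion] = []
    labels = label_map.labels
    for lid in label_map.ids():
        idx = np.argwhere(labels == lid)
        suvs = volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        hottest = idx[int(np.argmax(suvs))]
        suv_max = float(suvs.max())
        suv_peak = min(compute_suv_peak(volume, hottest, peak_sphere_cc), suv_max)
        if site_map is not None:
            site = _majority_site(site_map.labels[idx[:, 0], idx[:, 1], idx[:, 2]])
        else:
            site = "other"
        score = None if scores is None else scores.get(lid)
        lesions.append(
            Lesion(
                id=lid,
                volume_cc=len(idx) * vox_cc,
                suv_max=suv_max,
                suv_peak=suv_peak,
                site=site,
                provenance=provenance,
                score=score,
            )
        )
    return LesionSet(lesions=lesions, label_map=label_map, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Lesion tables

TABLE_COLUMNS = [
    "patient_id",
    "lesion_id",
    "provenance",
    "site",
    "volume_cc",
    "suv_max",
    "suv_peak",
    "score",
]


def lesion_table(sets: Iterable[LesionSet]) -> pd.DataFrame:
    """Flatten LesionSets into the canonical lesion-table DataFrame."""
    rows = []
    for ls in sets:
        for l in ls.lesions:
            rows.append(
                {
                    "patient_id": ls.patient_id,
                    "lesion_id": l.id,
                    "provenance": l.provenance,
                    "site": l.site,
                    "volume_cc": l.volume_cc,
                    "suv_max": l.suv_max,
                    "suv_peak": l.suv_peak,
                    "score": np.nan if l.score is None else l.score,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_lesion_table(sets: Iterable[LesionSet], path: str | Path) -> None:
    lesion_table(sets).to_csv(path, index=False)


def read_lesion_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: lesion table missing columns {missing}")
    return df
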