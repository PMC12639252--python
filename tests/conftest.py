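"""Shared fixtures: tiny phantoms and hand-built lesion worlds."""

from __future__ import annotations

import numpy as np
import pytest

from petlesion import (
    LabelMap,
    LesionSpec,
    PhantomSpec,
    SuvVolume,
    extract_lesions,
    generate_phantom,
)


@pytest.fixture
def one_lesion_phantom():
    """One 9 mm bone lesion (SUVmax 8) on a 64-cube at 3 mm voxels."""
    spec = PhantomSpec(
        lesions=(LesionSpec(center=(32, 32, 20), radius_mm=9.0, suv_max=8.0, site="bone"),),
        seed=7,
    )
    return generate_phantom(spec)


def gaussian_blob_volume(vox_mm: float, sigma_mm: float = 6.0, amplitude: float = 10.0,
                         fov_mm: float = 96.0) -> SuvVolume:
    """Isolated Gaussian blob centred exactly on a voxel (odd grid)."""
    n = int(round(fov_mm / vox_mm)) | 1
    ax = (np.arange(n) - n // 2) * vox_mm
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    v = amplitude * np.exp(-(x**2 + y**2 + z**2) / (2.0 * sigma_mm**2))
    return SuvVolume(values=v.astype(np.float32), spacing=(vox_mm,) * 3)


def voxel_world(expert_voxels, model_voxels, shape=(12, 12, 12), spacing=(5.0, 5.0, 5.0),
                model_scores=None, suv=None):
    """Build expert/model LesionSets from explicit voxel lists.

    ``expert_voxels``/``model_voxels`` map lesion id -> list of (i, j, k).
    """
    e = np.zeros(shape, dtype=np.int32)
    m = np.zeros(shape, dtype=np.int32)
    for lid, voxels in expert_voxels.items():
        for v in voxels:
            e[v] = lid
    for lid, voxels in model_voxels.items():
        for v in voxels:
            m[v] = lid
    values = np.ones(shape, dtype=np.float32) if suv is None else suv
    vol = SuvVolume(values=values, spacing=spacing)
    expert = extract_lesions(LabelMap(e, spacing), vol, provenance="expert")
    scores = model_scores
    if scores is None:
        scores = {lid: 0.9 for lid in model_voxels}
    model = extract_lesions(LabelMap(m, spacing), vol, provenance="model", scores=scores)
    return expert, model


def random_toy_instance(rng: np.random.Generator, grid: int = 16, max_lesions: int = 5):
    """Random overlapping expert/model boxes for correspondence stress tests.

    Lesions on one side never overlap each other (labels overwrite would
    break the truth); boxes are placed by rejection.
    """
    shape = (grid, grid, grid)

    def one_side():
        labels = np.zeros(shape, dtype=np.int32)
        n = int(rng.integers(1, max_lesions + 1))
        lid = 1
        for _ in range(n):
            for _try in range(30):
                size = rng.integers(1, 5, size=3)
                lo = [int(rng.integers(0, grid - s + 1)) for s in size]
                sl = tuple(slice(l, l + int(s)) for l, s in zip(lo, size))
                if (labels[sl] == 0).all():
                    labels[sl] = lid
                    lid += 1
                    break
        return labels

    e = one_side()
    m = one_side()
    expert_voxels = {int(i): [tuple(v) for v in np.argwhere(e == i)] for i in np.unique(e) if i}
    model_voxels = {int(i): [tuple(v) for v in np.argwhere(m == i)] for i in np.unique(m) if i}
    scores = {lid: float(rng.uniform(0, 1)) for lid in model_voxels}
    return voxel_world(expert_voxels, model_voxels, shape=shape, spacing=(4.0, 4.0, 4.0),
                       model_scores=scores)
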