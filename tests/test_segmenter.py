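"""Adaptive-threshold segmenter: detection, contouring, filtering."""

import numpy as np
import pytest

from petlesion import (
    BloodPoolStats,
    LabelMap,
    SegmenterConfig,
    SuvVolume,
    blood_pool_stats,
    detect_foci,
    segment_focus,
    segment_volume,
)
from petlesion.synthetic import LesionSpec, PhantomSpec, generate_phantom

from conftest import gaussian_blob_volume


def _sphere_volume(vals, spacing=(2.0, 2.0, 2.0)):
    return SuvVolume(values=vals.astype(np.float32), spacing=spacing)


class TestBloodPoolStats:
    def test_constant_region(self):
        vol = _sphere_volume(np.full((4, 4, 4), 1.5))
        mask = LabelMap(np.ones((4, 4, 4), dtype=np.int32), (2, 2, 2))
        bp = blood_pool_stats(vol, mask)
        assert bp.mean_bp == pytest.approx(1.5)
        assert bp.sd_bp == pytest.approx(0.0)

    def test_sample_sd_uses_n_minus_1(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [1.0, 2.0, 3.0]
        mask = LabelMap(np.ones((3, 1, 1), dtype=np.int32), (2, 2, 2))
        bp = blood_pool_stats(_sphere_volume(vals), mask)
        assert bp.mean_bp == pytest.approx(2.0)
        assert bp.sd_bp == pytest.approx(1.0)  # sample SD of {1,2,3}

    def test_recovers_generator_parameters(self):
        rng = np.random.default_rng(42)
        vals = np.abs(rng.normal(1.8, 0.15, (10, 10, 10)))
        mask = LabelMap(np.ones((10, 10, 10), dtype=np.int32), (2, 2, 2))
        bp = blood_pool_stats(_sphere_volume(vals), mask)
        assert bp.mean_bp == pytest.approx(1.8, abs=0.02)
        assert bp.n_voxels == 1000

    def test_tiny_mask_rejected(self):
        vol = _sphere_volume(np.ones((4, 4, 4)))
        mask = np.zeros((4, 4, 4), dtype=np.int32)
        mask[0, 0, 0] = 1
        with pytest.raises(ValueError):
            blood_pool_stats(vol, LabelMap(mask, (2, 2, 2)))


def _hot_sphere(shape, center, radius_vox, amplitude, background=1.0, blur_vox=1.5):
    from scipy import ndimage

    vals = np.full(shape, background)
    idx = np.indices(shape)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    vals[d2 <= radius_vox**2] = amplitude
    return ndimage.gaussian_filter(vals, blur_vox)


class TestDetectFoci:
    BP = BloodPoolStats(mean_bp=1.8, sd_bp=0.15, n_voxels=1000)

    def test_uniform_background_yields_nothing(self):
        vol = _sphere_volume(np.ones((12, 12, 12)))
        assert detect_foci(vol, self.BP) == []

    def test_single_blurred_sphere_gives_one_focus_at_hottest_voxel(self):
        vals = _hot_sphere((24, 24, 24), (12, 12, 12), 3, 8.0)
        vol = _sphere_volume(vals)
        foci = detect_foci(vol, self.BP)
        assert len(foci) == 1
        # brute-force oracle: the global argmax
        assert foci[0] == tuple(np.unravel_index(np.argmax(vol.values), vol.shape))

    def test_two_separated_spheres_give_two_foci(self):
        vals = _hot_sphere((32, 32, 32), (8, 8, 8), 3, 8.0)
        vals += _hot_sphere((32, 32, 32), (24, 24, 24), 3, 6.0) - 1.0
        vol = _sphere_volume(vals)
        foci = detect_foci(vol, self.BP)
        assert len(foci) == 2
        # sorted by descending SUVpeak: hotter sphere first
        assert vol.values[foci[0]] > vol.values[foci[1]]

    def test_focus_count_non_increasing_in_sd_multiplier(self):
        rng = np.random.default_rng(1)
        vals = _hot_sphere((24, 24, 24), (12, 12, 12), 3, 8.0)
        vals += rng.normal(0, 0.05, vals.shape)
        vol = _sphere_volume(np.abs(vals))
        counts = [
            len(detect_foci(vol, self.BP, SegmenterConfig(detection_sd_multiplier=k)))
            for k in (0.0, 1.0, 2.0, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSegmentFocus:
    def test_hard_sphere_fully_contoured(self):
        shape = (20, 20, 20)
        idx = np.indices(shape)
        d2 = sum((idx[a] - 10) ** 2 for a in range(3))
        vals = np.where(d2 <= 16, 10.0, 0.0)
        vol = _sphere_volume(vals)
        mask = segment_focus(vol, (10, 10, 10))
        np.testing.assert_array_equal(mask, d2 <= 16)

    def test_gaussian_blob_matches_isocontour_volume(self):
        vol = gaussian_blob_volume(2.0)
        mask = segment_focus(vol, tuple(s // 2 for s in vol.shape))
        measured = mask.sum() * vol.voxel_volume_cc
        sigma = 6.0
        expected = 4 / 3 * np.pi * (np.sqrt(-2 * np.log(0.42)) * sigma) ** 3 / 1000
        assert measured == pytest.approx(expected, rel=0.15)

    def test_touching_foci_yield_one_shared_component(self):
        shape = (30, 20, 20)
        idx = np.indices(shape)
        d2a = (idx[0] - 12) ** 2 + (idx[1] - 10) ** 2 + (idx[2] - 10) ** 2
        d2b = (idx[0] - 18) ** 2 + (idx[1] - 10) ** 2 + (idx[2] - 10) ** 2
        vals = np.maximum(np.where(d2a <= 16, 10.0, 0.0), np.where(d2b <= 16, 9.0, 0.0))
        vol = _sphere_volume(vals)
        mask_a = segment_focus(vol, (12, 10, 10))
        mask_b = segment_focus(vol, (18, 10, 10))
        np.testing.assert_array_equal(mask_a, mask_b)

    def test_volume_non_increasing_in_threshold_fraction(self):
        vol = gaussian_blob_volume(2.0)
        center = tuple(s // 2 for s in vol.shape)
        vols = [
            segment_focus(vol, center, SegmenterConfig(threshold_fraction=f)).sum()
            for f in (0.2, 0.3, 0.42, 0.6, 0.8)
        ]
        assert vols == sorted(vols, reverse=True)

    def test_focus_outside_grid_rejected(self):
        vol = _sphere_volume(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            segment_focus(vol, (9, 0, 0))


class TestSegmentVolume:
    def test_phantom_lesion_recovered(self, one_lesion_phantom):
        ph = one_lesion_phantom
        ls = segment_volume(ph.volume, ph.blood_pool_mask, ph.site_map)
        assert len(ls) == 1
        lesion = ls.lesions[0]
        assert lesion.site == "bone"
        # 9 mm sphere is ~3.05 cc; PET-threshold contour lands near truth
        assert lesion.volume_cc == pytest.approx(ph.truth.volume_cc[0], rel=0.4)

    def test_sub_half_cc_lesion_excluded(self):
        # hard 0.4 cc cube (50 voxels at 2 mm) on cold background
        vals = np.ones((24, 24, 24)) * 0.1
        vals[10:15, 10:15, 10:12] = 8.0  # 50 voxels = 0.4 cc
        vol = _sphere_volume(vals)
        bp = np.zeros((24, 24, 24), dtype=np.int32)
        bp[0:4, 0:4, 0:4] = 1
        ls = segment_volume(vol, LabelMap(bp, (2, 2, 2)),
                            cfg=SegmenterConfig(min_volume_cc=0.5))
        assert len(ls) == 0

    def test_exactly_half_cc_retained(self):
        vals = np.ones((24, 24, 24)) * 0.1
        vals[10:15, 10:15, 10:12] = 8.0
        vol = _sphere_volume(vals)
        bp = np.zeros((24, 24, 24), dtype=np.int32)
        bp[0:4, 0:4, 0:4] = 1
        ls = segment_volume(vol, LabelMap(bp, (2, 2, 2)),
                            cfg=SegmenterConfig(min_volume_cc=0.4))
        assert len(ls) == 1
        assert ls.lesions[0].volume_cc >= 0.4

    def test_all_background_phantom_empty(self):
        spec = PhantomSpec(seed=9)
        ph = generate_phantom(spec)
        ls = segment_volume(ph.volume, ph.blood_pool_mask, ph.site_map)
        assert len(ls) == 0

    def test_emitted_lesions_are_voxel_disjoint(self):
        spec = PhantomSpec(
            lesions=(
                LesionSpec(center=(20, 20, 20), radius_mm=8.0, suv_max=9.0, site="liver"),
                LesionSpec(center=(30, 30, 30), radius_mm=7.0, suv_max=6.0, site="lung"),
                LesionSpec(center=(44, 20, 30), radius_mm=6.0, suv_max=7.0, site="bone"),
            ),
            seed=5,
        )
        ph = generate_phantom(spec)
        ls = segment_volume(ph.volume, ph.blood_pool_mask, ph.site_map)
        labels = ls.label_map.labels
        assert len(ls) >= 2
        # disjointness is structural (one label per voxel); check IDs ordered
        # by descending SUVmax as promised
        suvs = [ls[i].suv_max for i in sorted(l.id for l in ls.lesions)]
        assert suvs == sorted(suvs, reverse=True)
        assert set(np.unique(labels)) == {0, *[l.id for l in ls.lesions]}
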