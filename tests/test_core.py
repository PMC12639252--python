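"""Data model, NIfTI round-trips and lesion feature extraction."""

import numpy as np
import pytest

import nibabel as nib
from petlesion import (
    LabelMap,
    SuvVolume,
    compute_suv_peak,
    extract_lesions,
    read_label_map,
    read_suv_volume,
    voxel_volume_cc,
    write_label_map,
    write_suv_volume,
)
from petlesion.core import FormatError, SITE_TO_CODE


@pytest.mark.parametrize(
    "spacing, expected",
    [((10, 10, 10), 1.0), ((2, 2, 2), 0.008), ((2, 2, 3), 0.012)],
)
def test_voxel_volume_cc(spacing, expected):
    assert voxel_volume_cc(spacing) == pytest.approx(expected)


@pytest.mark.parametrize("spacing", [(0, 1, 1), (-2, 2, 2), (1, 1)])
def test_voxel_volume_rejects_bad_spacing(spacing):
    with pytest.raises(ValueError):
        voxel_volume_cc(spacing)


def test_suv_volume_rejects_negative_and_nonfinite():
    with pytest.raises(ValueError):
        SuvVolume(values=-np.ones((2, 2, 2)), spacing=(1, 1, 1))
    bad = np.ones((2, 2, 2))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        SuvVolume(values=bad, spacing=(1, 1, 1))


class TestNiftiIO:
    def test_round_trip_identity(self, tmp_path):
        vol = SuvVolume(values=np.ones((4, 4, 4), dtype=np.float32), spacing=(2, 2, 2))
        path = tmp_path / "vol.nii.gz"
        write_suv_volume(vol, path)
        back = read_suv_volume(path)
        assert back.shape == (4, 4, 4)
        assert back.spacing == (2.0, 2.0, 2.0)
        np.testing.assert_array_equal(back.values, vol.values)

    def test_round_trip_preserves_float32_values(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = SuvVolume(values=rng.gamma(2.0, 1.0, (6, 5, 4)).astype(np.float32),
                        spacing=(2.0, 2.5, 3.0))
        write_suv_volume(vol, tmp_path / "v.nii")
        back = read_suv_volume(tmp_path / "v.nii")
        np.testing.assert_array_equal(back.values, vol.values)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_label_map_round_trip(self, tmp_path):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[1:3, 1:3, 1:3] = 2
        lm = LabelMap(labels=labels, spacing=(1.5, 1.5, 2.0))
        write_label_map(lm, tmp_path / "l.nii.gz")
        back = read_label_map(tmp_path / "l.nii.gz")
        np.testing.assert_array_equal(back.labels, labels)
        assert back.ids() == [2]

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_suv_volume(tmp_path / "absent.nii")

    def test_non_3d_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.ones((4, 4), dtype=np.float32), np.eye(4))
        nib.save(img, str(tmp_path / "flat.nii"))
        with pytest.raises(FormatError, match="dim"):
            read_suv_volume(tmp_path / "flat.nii")

    def test_nonpositive_pixdim_rejected(self, tmp_path):
        import struct

        img = nib.Nifti1Image(np.ones((4, 4, 4), dtype=np.float32), np.eye(4))
        path = tmp_path / "bad.nii"
        nib.save(img, str(path))
        # corrupt pixdim[1] in place (byte offset 80 of the NIfTI-1 header);
        # nibabel silently repairs negative or zero pixdim, NaN survives
        raw = bytearray(path.read_bytes())
        raw[80:84] = struct.pack("<f", float("nan"))
        path.write_bytes(bytes(raw))
        with pytest.raises(FormatError, match="pixdim"):
            read_suv_volume(path)


class TestSuvPeak:
    def test_uniform_field_gives_constant(self):
        vol = SuvVolume(values=np.full((11, 11, 11), 3.5, dtype=np.float32), spacing=(2, 2, 2))
        assert compute_suv_peak(vol, (5, 5, 5), 1.0) == pytest.approx(3.5)

    def test_single_hot_voxel_is_diluted_by_sphere(self):
        # brute-force oracle: count voxel centers inside the 1 cc sphere
        # (r = 6.20 mm); 123 voxels x 8 mm^3 = 984 mm^3, consistent with 1 cc
        spacing = (2.0, 2.0, 2.0)
        r = (3 * 1000 / (4 * np.pi)) ** (1 / 3)
        n = 0
        for i in range(-4, 5):
            for j in range(-4, 5):
                for k in range(-4, 5):
                    if (2 * i) ** 2 + (2 * j) ** 2 + (2 * k) ** 2 <= r**2:
                        n += 1
        assert n == 123
        vals = np.zeros((15, 15, 15), dtype=np.float32)
        vals[7, 7, 7] = 10.0
        vol = SuvVolume(values=vals, spacing=spacing)
        assert compute_suv_peak(vol, (7, 7, 7), 1.0) == pytest.approx(10.0 / n)

    def test_center_outside_grid_rejected(self):
        vol = SuvVolume(values=np.ones((4, 4, 4)), spacing=(2, 2, 2))
        with pytest.raises(ValueError):
            compute_suv_peak(vol, (4, 0, 0), 1.0)


class TestExtractLesions:
    def test_uniform_region_volume_and_suvmax(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        flat = np.arange(100)
        labels.ravel()[flat] = 1  # 100 voxels at 2 mm -> 0.8 cc
        vals = np.where(labels > 0, 5.0, 0.0).astype(np.float32)
        ls = extract_lesions(LabelMap(labels, (2, 2, 2)), SuvVolume(vals, (2, 2, 2)))
        assert len(ls) == 1
        assert ls[1].volume_cc == pytest.approx(0.8)
        assert ls[1].suv_max == pytest.approx(5.0)
        assert ls[1].suv_peak <= ls[1].suv_max

    def test_two_disjoint_labels_get_independent_stats(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[0:2, 0:2, 0:2] = 1
        labels[5:8, 5:8, 5:8] = 2
        vals = np.where(labels == 1, 4.0, np.where(labels == 2, 9.0, 0.0))
        ls = extract_lesions(LabelMap(labels, (2, 2, 2)), SuvVolume(vals, (2, 2, 2)))
        assert ls[1].suv_max == pytest.approx(4.0)
        assert ls[2].suv_max == pytest.approx(9.0)
        assert ls[1].volume_cc == pytest.approx(8 * 0.008)
        assert ls[2].volume_cc == pytest.approx(27 * 0.008)

    def test_majority_site_with_brute_force_count(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[0, 0, :10] = 1
        sites = np.zeros((10, 10, 10), dtype=np.int32)
        sites[0, 0, :6] = SITE_TO_CODE["liver"]   # 60 %
        sites[0, 0, 6:10] = SITE_TO_CODE["bone"]  # 40 %
        vals = np.ones((10, 10, 10), dtype=np.float32)
        ls = extract_lesions(LabelMap(labels, (2, 2, 2)), SuvVolume(vals, (2, 2, 2)),
                             site_map=LabelMap(sites, (2, 2, 2)))
        # oracle: liver carries 6 of 10 voxels
        assert ls[1].site == "liver"

    def test_site_tie_breaks_to_first_name(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, :4] = 1
        sites = np.zeros((4, 4, 4), dtype=np.int32)
        sites[0, 0, :2] = SITE_TO_CODE["liver"]
        sites[0, 0, 2:4] = SITE_TO_CODE["bone"]
        ls = extract_lesions(LabelMap(labels, (2, 2, 2)),
                             SuvVolume(np.ones((4, 4, 4)), (2, 2, 2)),
                             site_map=LabelMap(sites, (2, 2, 2)))
        assert ls[1].site == "bone"  # 'bone' < 'liver'

    def test_empty_label_map_gives_empty_set(self):
        ls = extract_lesions(LabelMap(np.zeros((4, 4, 4), dtype=np.int32), (2, 2, 2)),
                             SuvVolume(np.ones((4, 4, 4)), (2, 2, 2)))
        assert len(ls) == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_lesions(LabelMap(np.zeros((4, 4, 4), dtype=np.int32), (2, 2, 2)),
                            SuvVolume(np.ones((5, 5, 5)), (2, 2, 2)))

    def test_volume_sum_matches_nonzero_voxel_count_exactly(self, one_lesion_phantom):
        ph = one_lesion_phantom
        ls = ph.expert_lesion_set()
        total = sum(l.volume_cc for l in ls.lesions)
        nonzero = int((ph.expert_labels.labels > 0).sum())
        assert total == pytest.approx(nonzero * ph.expert_labels.voxel_volume_cc, abs=1e-12)

    def test_relabeling_permutes_ids_but_not_stats(self):
        rng = np.random.default_rng(3)
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[0:3, 0:3, 0:3] = 1
        labels[6:9, 6:9, 6:9] = 2
        vals = rng.gamma(2.0, 1.0, (10, 10, 10)).astype(np.float32)
        vol = SuvVolume(vals, (2, 2, 2))
        a = extract_lesions(LabelMap(labels, (2, 2, 2)), vol)
        swapped = np.where(labels == 1, 2, np.where(labels == 2, 1, 0)).astype(np.int32)
        b = extract_lesions(LabelMap(swapped, (2, 2, 2)), vol)
        for src, dst in [(1, 2), (2, 1)]:
            assert a[src].volume_cc == b[dst].volume_cc
            assert a[src].suv_max == b[dst].suv_max
            assert a[src].suv_peak == b[dst].suv_peak
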