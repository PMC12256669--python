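import numpy as np
import pytest

import mlemlab as ml
from mlemlab.phantoms import orientation_matrix


class TestMakeDisk:
    def test_sharp_disk_is_binary(self):
        img = ml.make_disk(128, 40, 1.0, 0)
        assert set(np.unique(img.values)) <= {0.0, 1.0}
        assert img.values[63, 63] == 1.0

    def test_blur_preserves_total_intensity(self):
        sharp = ml.make_disk(128, 40, 1.0, 0)
        blurred = ml.make_disk(128, 40, 1.0, 2)
        assert abs(blurred.values.sum() - sharp.values.sum()) / sharp.values.sum() < 1e-3

    def test_blur_does_not_overshoot_and_edge_is_monotone(self):
        img = ml.make_disk(128, 40, 1.0, 5)
        assert img.values.max() < 1.0
        # radially monotone: along the center row, values rise toward center
        half_row = img.values[63, :64]
        assert np.all(np.diff(half_row) >= -1e-12)

    def test_disk_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            ml.make_disk(64, 70, 1.0, 0)


class TestMakeCheckerboard:
    def test_half_the_pixels_are_high(self):
        img = ml.make_checkerboard(256, 32, 0.0, 1.0)
        assert (img.values == 1.0).sum() == 256 * 256 // 2

    @pytest.mark.parametrize("ratio,center", [(2.0, None), (5.0, (76.0, 76.0))])
    def test_spot_value_is_ratio_times_high(self, ratio, center):
        spot = ml.SpotSpec(shape="disk", intensity_ratio=ratio,
                           diameter_px=32, center=center)
        img = ml.make_checkerboard(256, 32, 0.0, 1.0, spot)
        assert img.values.max() == ratio
        ci, cj = center if center is not None else (127.5, 127.5)
        peak = np.argwhere(img.values == ratio)
        assert np.all(np.hypot(peak[:, 0] - ci, peak[:, 1] - cj) <= 16.5)

    def test_non_divisible_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ml.make_checkerboard(100, 32, 0.0, 1.0)

    def test_deterministic(self):
        a = ml.make_checkerboard(64, 16, 0.0, 1.0)
        b = ml.make_checkerboard(64, 16, 0.0, 1.0)
        assert np.array_equal(a.values, b.values)


class TestCardiacPhantom:
    def test_lesion_ratio_sets_max_voxel(self, cardiac96):
        ctrl, hot = cardiac96
        assert hot.values.max() == pytest.approx(300.0)
        assert ctrl.values.max() == pytest.approx(75.0)
        # lesion / myocardium equals the intensity ratio exactly
        assert hot.meta["lesion_value"] / 75.0 == 4.0

    def test_lesion_extent_matches_diameter(self, cardiac96):
        _, hot = cardiac96
        vs = hot.voxel_size_mm
        ic = np.round(hot.meta["lesion_center_mm"] / vs
                      + (np.array(hot.shape) - 1) / 2).astype(int)
        row = hot.values[:, ic[1], ic[2]]
        n = int((row >= (hot.meta["lesion_value"] + 0.5) / 2).sum())
        assert n in (12, 13)  # 30 mm at 2.34 mm voxels

    def test_lesion_overlapping_myocardium_rejected(self):
        lesion = ml.SpotSpec(shape="sphere", intensity_ratio=2.0,
                             diameter_mm=30.0, reference="myocardium")
        spec = ml.CardiacPhantomSpec(matrix=(96, 96, 96), lesion=lesion,
                                     lesion_gap_mm=-20.0)
        with pytest.raises(ValueError, match="overlap"):
            ml.make_cardiac_phantom(spec)

    def test_spec_yaml_roundtrip(self):
        lesion = ml.SpotSpec(shape="sphere", intensity_ratio=2.0,
                             diameter_mm=30.0, reference="myocardium")
        spec = ml.CardiacPhantomSpec(matrix=(96, 96, 96), lesion=lesion)
        again = ml.CardiacPhantomSpec.from_yaml(spec.to_yaml())
        assert again == spec


class TestRotateVolume:
    def test_full_turn_recovers_volume(self, cardiac96):
        _, hot = cardiac96
        back = ml.rotate_volume(hot, "y", 360.0)
        rel = np.sqrt(np.mean((back.values - hot.values) ** 2)
                      / np.mean(hot.values ** 2))
        assert rel < 1e-3

    def test_rotation_and_inverse(self, cardiac96):
        _, hot = cardiac96
        back = ml.rotate_volume(ml.rotate_volume(hot, "y", 90.0), "y", -90.0)
        rel = np.sqrt(np.mean((back.values - hot.values) ** 2)
                      / np.mean(hot.values ** 2))
        assert rel < 1e-2

    def test_y_rotation_separates_lesion_and_lv_along_z(self, cardiac96):
        _, hot = cardiac96
        rot = ml.rotate_volume(hot, "y", 90.0)

        def zc(vol, lo, hi):
            m = (vol.values > lo) & (vol.values < hi)
            return np.array(np.nonzero(m)).mean(axis=1)[2]

        sep = abs(zc(rot, 200, 400) - zc(rot, 50, 100)) * hot.voxel_size_mm
        assert sep > hot.meta["lesion_radius_mm"]

    def test_rotation_conserves_intensity(self, cardiac96):
        ctrl, _ = cardiac96
        rot = ml.rotate_volume(ctrl, "x", 37.0)
        assert abs(rot.values.sum() - ctrl.values.sum()) / ctrl.values.sum() < 0.01

    def test_invalid_axis_rejected(self, cardiac96):
        ctrl, _ = cardiac96
        with pytest.raises(ValueError, match="axis"):
            ml.rotate_volume(ctrl, "w", 10.0)


class TestReorient:
    def test_identity_orientation_is_noop(self, cardiac96):
        ctrl, _ = cardiac96
        out = ml.reorient_to_cardiac_axes(ctrl, (0, 0, 0))
        assert np.array_equal(out.values, ctrl.values)

    def test_short_axis_slice_is_annulus(self, cardiac96):
        ctrl, _ = cardiac96
        re = ml.reorient_to_cardiac_axes(ctrl, (-90, -20, -50))
        N = 96
        sl = re.values[:, N // 2, :]  # LV long axis lies along y after reorienting
        c = (N - 1) / 2
        ii, jj = np.indices(sl.shape)
        rb = np.hypot(ii - c, jj - c).astype(int)
        prof = np.bincount(rb.ravel(), sl.ravel()) / np.bincount(rb.ravel())
        wall = np.argmax(prof[:30])
        # single peak at the wall radius, cavity and outside dim
        assert 7 <= wall <= 13
        assert prof[wall] > 50
        assert prof[2] < 10 and prof[20] < 10

    def test_reorient_matches_aligned_construction(self):
        lesion = ml.SpotSpec(shape="sphere", intensity_ratio=4.0,
                             diameter_mm=30.0, reference="myocardium")
        kw = dict(matrix=(96, 96, 96), lesion=lesion, background_value=0.0,
                  myocardium_value=75.0)
        oriented = ml.make_cardiac_phantom(ml.CardiacPhantomSpec(**kw))
        aligned = ml.make_cardiac_phantom(
            ml.CardiacPhantomSpec(orientation_deg=(0, 0, 0), **kw))
        re = ml.reorient_to_cardiac_axes(oriented, (-90, -20, -50))
        rel = np.sqrt(np.mean((re.values - aligned.values) ** 2)
                      / np.mean(aligned.values ** 2))
        assert rel < 0.05


def test_orientation_matrix_is_rotation():
    R = orientation_matrix((-90.0, -20.0, -50.0))
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
    assert np.linalg.det(R) == pytest.approx(1.0)
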