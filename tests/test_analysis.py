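import numpy as np
import pytest
from skimage import measure

import mlemlab as ml
from mlemlab.analysis import sector_masks


class TestSegmentLV:
    def test_bimodal_threshold_between_levels(self):
        vals = np.zeros((64, 64))
        vals[:, 32:] = 75.0
        mask = ml.segment_lv(ml.Image2D(vals), resize_scale=1)
        assert 0.0 < mask.threshold < 75.0

    def test_annulus_mask_topology(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=2)
        # one connected component enclosing one hole: Euler characteristic 0
        assert measure.euler_number(mask.mask, connectivity=1) == 0

    def test_scale_consistency(self, annulus_slice):
        m1 = ml.segment_lv(annulus_slice, resize_scale=1)
        m6 = ml.segment_lv(annulus_slice, resize_scale=6)
        down = m6.mask.reshape(96, 6, 96, 6).mean(axis=(1, 3)) > 0.5
        inter = np.logical_and(down, m1.mask).sum()
        dice = 2 * inter / (down.sum() + m1.mask.sum())
        assert dice > 0.9

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            ml.segment_lv(ml.Image2D(np.zeros((32, 32))), resize_scale=1)


class TestNormalizeToLV:
    def test_max_inside_mask_is_one(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        out = ml.normalize_to_lv(annulus_slice, mask)
        assert out.values[mask.mask].max() == pytest.approx(1.0)

    def test_scale_invariance(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        a = ml.normalize_to_lv(annulus_slice, mask)
        b = ml.normalize_to_lv(ml.Image2D(annulus_slice.values * 7), mask)
        assert np.allclose(a.values, b.values)

    def test_hot_lesion_outside_mask_does_not_change_normalization(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        hot = annulus_slice.values.copy()
        hot[2:6, 2:6] = 500.0  # intense spot far outside the ring
        a = ml.normalize_to_lv(annulus_slice, mask)
        b = ml.normalize_to_lv(ml.Image2D(hot), mask)
        assert np.allclose(a.values[mask.mask], b.values[mask.mask])


class TestErrorImage:
    def test_control_vs_itself_is_zero(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        n = ml.normalize_to_lv(annulus_slice, mask)
        em = ml.error_image(n, n, mask)
        assert np.all(em.values == 0)

    def test_uniform_suppression_is_linear(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        n = ml.normalize_to_lv(annulus_slice, mask)
        idx = ml.Image2D(n.values * 0.8, n.pixel_size_mm)
        em = ml.error_image(n, idx, mask)
        assert np.allclose(em.values[mask.mask], 0.2 * n.values[mask.mask])

    def test_antisymmetric_under_swap(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        a = ml.normalize_to_lv(annulus_slice, mask)
        rng = np.random.default_rng(0)
        b = ml.Image2D(np.clip(a.values + 0.1 * rng.standard_normal(a.values.shape),
                               0, None), a.pixel_size_mm)
        e1 = ml.error_image(a, b, mask)
        e2 = ml.error_image(b, a, mask)
        assert np.allclose(e1.values, -e2.values)


class TestSectors:
    def test_sectors_partition_the_mask(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        sects = sector_masks(mask, lateral_angle_deg=40.0)
        total = np.zeros_like(mask.mask, dtype=int)
        for m in sects.values():
            total += m
        assert np.all(total[mask.mask] == 1)
        assert np.all(total[~mask.mask] == 0)

    def test_wall_error_summary_zero_for_control(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        n = ml.normalize_to_lv(annulus_slice, mask)
        em = ml.error_image(n, n, mask)
        table = ml.wall_error_summary({"ctrl": em}, lateral_angle_deg=0.0)
        assert (table.mean_abs_error == 0).all()
        assert set(table.sector) == {"lateral", "anterior", "septal", "inferior"}


class TestCircumferentialProfile:
    def test_uniform_annulus_gives_flat_curve(self, annulus_slice):
        flat = ml.Image2D(np.where(annulus_slice.values > 1, 1.0, 0.0))
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        prof = ml.circumferential_profile(flat, mask, n_samples=72)
        assert np.allclose(prof.values, 1.0)

    def test_scaled_sector_dips(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        vals = np.where(annulus_slice.values > 1, 1.0, 0.0)
        ii, jj = np.indices(vals.shape)
        ang = np.degrees(np.arctan2(jj - 47.5, ii - 47.5))
        sector = np.abs(ang) <= 30
        vals[sector] *= 0.5
        prof = ml.circumferential_profile(ml.Image2D(vals), mask, n_samples=72)
        inside = np.abs(prof.positions) <= 25
        outside = np.abs(prof.positions) >= 40
        assert np.allclose(prof.values[inside], 0.5)
        assert np.allclose(prof.values[outside], 1.0)

    def test_center_on_wall_rejected(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        with pytest.raises(ValueError, match="cavity"):
            ml.circumferential_profile(annulus_slice, mask, n_samples=72,
                                       center=(47.5, 62.0))  # on the ring

    def test_too_few_samples_rejected(self, annulus_slice):
        mask = ml.segment_lv(annulus_slice, resize_scale=1)
        with pytest.raises(ValueError, match="36"):
            ml.circumferential_profile(annulus_slice, mask, n_samples=10)


class TestLineProfile:
    def test_constant_image_gives_constant_profile(self):
        img = ml.Image2D(np.full((32, 32), 3.0))
        prof = ml.line_profile(img, ((4.0, 4.0), (28.0, 20.0)))
        assert np.allclose(prof.values, 3.0)

    def test_row_index_profile(self):
        vals = np.zeros((32, 32))
        vals[10, :] = np.arange(32)
        prof = ml.line_profile(ml.Image2D(vals), 10)
        assert np.array_equal(prof.values, np.arange(32.0))

    def test_degenerate_line_rejected(self):
        img = ml.Image2D(np.ones((32, 32)))
        with pytest.raises(ValueError, match="zero-length"):
            ml.line_profile(img, ((5.0, 5.0), (5.0, 5.0)))


class TestGibbsOvershoot:
    def test_limit_value_with_many_harmonics(self):
        assert ml.gibbs_overshoot(1000) == pytest.approx(8.949, abs=0.01)

    def test_single_harmonic(self):
        assert ml.gibbs_overshoot(1) == pytest.approx(13.66, abs=0.01)

    def test_converges_from_above(self):
        o1 = ml.gibbs_overshoot(1)
        o2000 = ml.gibbs_overshoot(2000)
        assert o2000 <= o1
        assert o1 >= 8.9 and o2000 >= 8.9

    def test_invalid_terms_rejected(self):
        with pytest.raises(ValueError, match="n_terms"):
            ml.gibbs_overshoot(0)
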