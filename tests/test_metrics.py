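"""Dice, global SSIM, Pearson profile correlation, volumes, time traces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import pamreg as pr
from pamreg.metrics import ProfileLine, SSIMParams
from pamreg.volume import BinaryMask, ImageVolume


def brute_ssim(I, x, K1, K2, L):
    C1, C2 = (K1 * L) ** 2, (K2 * L) ** 2
    mi, mx = I.mean(), x.mean()
    vi, vx = I.var(), x.var()
    cov = np.mean((I - mi) * (x - mx))
    return (2 * mi * mx + C1) * (2 * cov + C2) / ((mi**2 + mx**2 + C1) * (vi + vx + C2))


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((2, 4, 4), bool)
        m[0, 1:3, 1:3] = True
        assert pr.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((1, 4, 4), bool)
        b = np.zeros((1, 4, 4), bool)
        a[0, 0, 0] = True
        b[0, 3, 3] = True
        assert pr.dice(a, b) == 0.0

    def test_half_overlap_by_hand(self):
        a = np.zeros((1, 4, 4), bool)
        b = np.zeros((1, 4, 4), bool)
        a[0, 0, :4] = True  # |X| = 4
        b[0, 0, 2:] = True
        b[0, 1, :2] = True  # |Y| = 4, |X^Y| = 2
        assert pr.dice(a, b) == pytest.approx(0.5)

    def test_empty_masks_score_one_with_warning(self):
        e = np.zeros((1, 2, 2), bool)
        with pytest.warns(UserWarning, match="empty"):
            assert pr.dice(e, e) == 1.0

    @given(hnp.arrays(bool, (6, 6)), hnp.arrays(bool, (6, 6)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, a, b):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1, d2 = pr.dice(a[None], b[None]), pr.dice(b[None], a[None])
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0


class TestSSIMGlobal:
    def test_self_similarity_is_one(self):
        img = np.random.default_rng(0).random((12, 12))
        assert pr.ssim_global(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_constant_pair_closed_form(self):
        a, b = 3.0, 5.0
        L = abs(a - b)
        got = pr.ssim_global(np.full((8, 8), a), np.full((8, 8), b),
                             SSIMParams(L=L))
        C1 = (0.01 * L) ** 2
        assert got == pytest.approx((2 * a * b + C1) / (a**2 + b**2 + C1), abs=1e-12)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            I = rng.random((8, 8))
            x = rng.random((8, 8))
            got = pr.ssim_global(I, x, SSIMParams(L=1.0))
            assert got == pytest.approx(brute_ssim(I, x, 0.01, 0.03, 1.0), abs=1e-12)
            assert got <= 1.0 + 1e-12

    def test_invariant_under_joint_pixel_permutation(self):
        rng = np.random.default_rng(7)
        I = rng.random((10, 10))
        x = rng.random((10, 10))
        perm = rng.permutation(100)
        got1 = pr.ssim_global(I, x)
        got2 = pr.ssim_global(I.ravel()[perm].reshape(10, 10),
                              x.ravel()[perm].reshape(10, 10))
        assert got1 == pytest.approx(got2, abs=1e-12)

    def test_windowed_variant_also_perfect_on_identical(self):
        img = np.random.default_rng(1).random((16, 16))
        assert pr.ssim_windowed(img, img) == pytest.approx(1.0, abs=1e-9)


class TestPearsonProfile:
    def _imgs(self):
        yy, xx = np.mgrid[:40, :40]
        return (yy + 2.0 * xx).astype(float)

    def test_identical_images_correlate_perfectly(self):
        img = self._imgs()
        line = ProfileLine((0.5, 0.2), (3.5, 3.8))
        assert pr.pearson_profile(img, img, line) == pytest.approx(1.0)

    def test_negated_image_anticorrelates(self):
        img = self._imgs()
        line = ProfileLine((0.5, 0.2), (3.5, 3.8))
        assert pr.pearson_profile(img, -img, line) == pytest.approx(-1.0)

    def test_exact_linear_relation(self):
        a = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (4, 1))
        line = ProfileLine((0.1, 0.0), (0.1, 0.3), step_mm=0.1)
        assert pr.pearson_profile(a, 2.0 * a, line) == pytest.approx(1.0)

    def test_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((30, 30)), rng.random((30, 30))
        line = ProfileLine((0.3, 0.3), (2.5, 2.2))
        r1 = pr.pearson_profile(a, b, line)
        r2 = pr.pearson_profile(3.0 * a + 1.0, 0.5 * b + 2.0, line)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_profile_rejected(self):
        img = np.ones((20, 20))
        line = ProfileLine((0.2, 0.2), (1.5, 1.5))
        with pytest.raises(ValueError, match="zero-variance"):
            pr.pearson_profile(img, img, line)

    def test_line_outside_image_rejected(self):
        img = np.ones((10, 10))
        with pytest.raises(ValueError, match="bounds"):
            pr.pearson_profile(img, img, ProfileLine((0, 0), (50.0, 50.0)))


class TestVolumesAndTraces:
    def test_empty_mask_zero_volume(self):
        assert pr.mask_volume(BinaryMask(np.zeros((2, 2, 2), bool))) == 0.0

    def test_hundred_voxels_at_known_spacing(self):
        data = np.zeros((4, 10, 10), bool)
        data[0, :10, :10] = True  # 100 voxels
        assert pr.mask_volume(BinaryMask(data, (1.0, 0.1, 0.1))) == pytest.approx(1.0)

    def test_constant_series_has_zero_changes(self):
        roi = BinaryMask(np.ones((1, 2, 2), bool))
        series = [ImageVolume(np.full((1, 2, 2), 7.0)) for _ in range(4)]
        trace = pr.roi_timetrace(series, roi)
        assert len(trace) == 4
        assert all(pct == 0.0 for _, _, pct in trace)

    def test_percent_change_convention(self):
        roi = BinaryMask(np.ones((1, 1, 1), bool))
        series = [ImageVolume(np.full((1, 1, 1), 10.0)),
                  ImageVolume(np.full((1, 1, 1), 13.912))]
        trace = pr.roi_timetrace(series, roi)
        assert trace[1][2] == pytest.approx(39.12)

    def test_empty_roi_rejected(self):
        roi = BinaryMask(np.zeros((1, 2, 2), bool))
        with pytest.raises(ValueError, match="empty ROI"):
            pr.roi_timetrace([ImageVolume(np.ones((1, 2, 2)))], roi)
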