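"""Marker profiles, Gaussian peak fitting and axial slice pairing."""

import numpy as np
import pytest

import pamreg as pr
from pamreg.axial import MarkerROI, MarkerProfile
from pamreg.volume import ImageVolume


def _profile(z, y):
    return MarkerProfile(np.asarray(z, float), np.asarray(y, float),
                         MarkerROI((0, 0), 1))


def _gauss(z, a, mu, sigma, b):
    return a * np.exp(-0.5 * ((np.asarray(z) - mu) / sigma) ** 2) + b


class TestProfileExtraction:
    def test_constant_volume_gives_flat_profile(self):
        vol = ImageVolume(np.full((6, 20, 20), 2.5), (0.3, 0.1, 0.1))
        p = pr.extract_marker_profile(vol, MarkerROI((10, 10), 3))
        assert np.allclose(p.mean_intensity, 2.5)
        assert len(p.mean_intensity) == 6

    def test_profile_peaks_at_marker_position(self, scene, pat_clean):
        m = scene.markers[0]
        my, mx = scene.marker_position_yx(m)
        roi = MarkerROI((my / 0.1 + 299 / 2, mx / 0.1 + 299 / 2), 5)
        p = pr.extract_marker_profile(pat_clean, roi)
        peak_z = p.slice_positions_mm[np.argmax(p.mean_intensity)]
        assert abs(peak_z - m.z_mm) <= pat_clean.spacing[0] / 2 + 1e-9

    def test_z_range_restricts_length(self):
        vol = ImageVolume(np.zeros((10, 8, 8)), (0.5, 0.1, 0.1))
        p = pr.extract_marker_profile(vol, MarkerROI((4, 4), 2), (1.0, 2.6))
        assert len(p.mean_intensity) == 4  # slices at 1.0, 1.5, 2.0, 2.5

    def test_empty_z_range_rejected(self):
        vol = ImageVolume(np.zeros((10, 8, 8)), (0.5, 0.1, 0.1))
        with pytest.raises(ValueError, match="z range"):
            pr.extract_marker_profile(vol, MarkerROI((4, 4), 2), (3.0, 3.0))


class TestGaussianFit:
    def test_exact_gaussian_recovered(self):
        z = np.arange(0, 15, 0.3)
        fit = pr.fit_gaussian(_profile(z, _gauss(z, 5.0, 7.3, 1.3, 0.4)))
        assert abs(fit.mean_mm - 7.3) < 1e-6
        assert abs(fit.sigma_mm - 1.3) < 1e-5
        assert fit.rmse < 1e-8

    def test_symmetric_profile_mean_at_centre(self):
        z = np.arange(5.0, 15.5, 0.5)
        y = _gauss(z, 2.0, 10.0, 2.0, 0.0)
        fit = pr.fit_gaussian(_profile(z, y))
        assert abs(fit.mean_mm - 10.0) < 1e-9

    def test_peak_stable_under_small_noise(self):
        rng = np.random.default_rng(11)
        z = np.arange(0, 12, 0.3)
        clean = _gauss(z, 5.0, 6.1, 1.3, 0.5)
        errs = []
        for _ in range(100):
            noisy = clean + rng.normal(0, 0.05, len(z))  # 1% of amplitude
            errs.append(abs(pr.fit_gaussian(_profile(z, noisy)).mean_mm - 6.1))
        assert np.median(errs) < 0.05

    def test_mean_invariant_to_affine_intensity_transform(self):
        z = np.arange(0, 12, 0.4)
        y = _gauss(z, 3.0, 5.0, 1.1, 0.2)
        f1 = pr.fit_gaussian(_profile(z, y))
        f2 = pr.fit_gaussian(_profile(z, 4.0 * y + 10.0))
        assert abs(f1.mean_mm - f2.mean_mm) < 1e-6

    def test_constant_profile_rejected(self):
        z = np.arange(6)
        with pytest.raises(ValueError, match="constant"):
            pr.fit_gaussian(_profile(z, np.ones(6)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            pr.fit_gaussian(_profile([0, 1, 2], [0, 1, 0]))


class TestMatching:
    def test_nearest_slice_and_offset(self):
        fit = pr.GaussianFit(1.0, 10.2, 1.0, 0.0, 0.0)
        idx, off = pr.match_axial(fit, 9.0, np.array([9.9, 10.2, 10.5]))
        assert idx == 1
        assert off == pytest.approx(1.2)

    def test_tie_breaks_to_lower_index(self):
        fit = pr.GaussianFit(1.0, 10.05, 1.0, 0.0, 0.0)
        idx, _ = pr.match_axial(fit, 10.0, np.array([9.9, 10.2]))
        assert idx == 0

    def test_out_of_range_peak_rejected(self):
        fit = pr.GaussianFit(1.0, 50.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="outside"):
            pr.match_axial(fit, 0.0, np.array([0.0, 1.0, 2.0]))

    @pytest.mark.parametrize("offsets,expected", [
        ([0.4], 0.4),
        ([0.3, 0.3, 5.0], 0.3),
        ([0.1, 0.2, 0.3], 0.2),
    ])
    def test_consensus_is_median(self, offsets, expected):
        assert pr.consensus_offset(offsets) == pytest.approx(expected)

    def test_consensus_requires_offsets(self):
        with pytest.raises(ValueError):
            pr.consensus_offset([])


class TestAlignStacks:
    def test_identity_mapping_on_identical_grids(self):
        vol = ImageVolume(np.zeros((8, 4, 4)), (0.5, 1, 1))
        assert np.array_equal(pr.align_stacks(vol, vol, 0.0), np.arange(8))

    def test_spacing_ratio_arithmetic(self):
        pat = ImageVolume(np.zeros((40, 4, 4)), (0.3, 1, 1))
        mri = ImageVolume(np.zeros((10, 4, 4)), (1.0, 1, 1))
        mapping = pr.align_stacks(pat, mri, 0.0)
        expected = np.round(np.arange(10) * 1.0 / 0.3).astype(int)
        assert np.array_equal(mapping, expected)

    def test_mapping_monotone(self):
        pat = ImageVolume(np.zeros((40, 4, 4)), (0.3, 1, 1))
        mri = ImageVolume(np.zeros((10, 4, 4)), (1.0, 1, 1))
        mapping = pr.align_stacks(pat, mri, 1.7)
        assert np.all(np.diff(mapping) >= 0)

    def test_no_overlap_rejected(self):
        pat = ImageVolume(np.zeros((5, 4, 4)), (0.3, 1, 1))
        mri = ImageVolume(np.zeros((5, 4, 4)), (1.0, 1, 1))
        with pytest.raises(ValueError, match="overlap"):
            pr.align_stacks(pat, mri, 100.0)


class TestEndToEnd:
    def test_offset_recovery_on_noiseless_phantom(self, scene, pat_clean, table):
        mri = pr.render_mri(scene, noise_sigma=0.0)
        true_offset = 1.2
        model = pr.MisalignmentModel(
            [pr.RigidTransform2D() for _ in range(mri.n_slices)],
            axial_offset_mm=true_offset)
        mri_mis = pr.apply_misalignment(mri, model)
        m = scene.markers[0]
        my, mx = scene.marker_position_yx(m)
        roi = MarkerROI((my / 0.1 + 299 / 2, mx / 0.1 + 299 / 2), 5)
        k = int(np.argmin(np.abs(mri_mis.slice_positions_mm() - (m.z_mm - true_offset))))
        mri_z = mri_mis.slice_positions_mm()[k]
        offset, pairing, recs = pr.register_axial(pat_clean, mri_mis, [(roi, mri_z)])
        assert abs(offset - true_offset) <= pat_clean.spacing[0] / 2
        # ground-truth pairing: nearest PAT slice to each true MRI position
        true_pos = mri.slice_positions_mm()
        pat_pos = pat_clean.volumes[0].slice_positions_mm()
        truth = np.argmin(np.abs(true_pos[:, None] - pat_pos[None, :]), axis=1)
        assert (pairing == truth).mean() >= 0.95
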