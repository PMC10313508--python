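"""Phantom generator: determinism, geometry, modality appearance, misalignment."""

import math

import numpy as np
import pytest

import pamreg as pr
from pamreg.phantom import Marker, default_scene


class TestRenderMRI:
    def test_deterministic_given_seed(self, scene):
        a = pr.render_mri(scene, noise_sigma=1.0)
        b = pr.render_mri(scene, noise_sigma=1.0)
        assert np.array_equal(a.data, b.data)

    def test_default_grid_and_spacing(self, mri_clean):
        assert mri_clean.shape[1:] == (250, 250)
        assert mri_clean.spacing == (1.0, 0.1, 0.1)

    def test_no_organs_gives_two_level_image(self):
        sc = pr.PhantomScene(z_extent_mm=4.0)
        v = pr.render_mri(sc, n_slices=4, noise_sigma=0.0)
        assert set(np.unique(v.data)) == {0.0, sc.body_mri_intensity}

    def test_grid_too_small_rejected(self, scene):
        with pytest.raises(ValueError, match="grid too small"):
            pr.render_mri(scene, grid=(50, 50))

    def test_marker_is_hypointense_on_its_slice(self, scene, mri_clean):
        m = scene.markers[0]
        k = int(round(m.z_mm / mri_clean.spacing[0]))
        my, mx = scene.marker_position_yx(m)
        r = int(my / 0.1 + 249 / 2), int(mx / 0.1 + 249 / 2)
        assert mri_clean.data[k, r[0], r[1]] == 0.0


class TestRenderPAT:
    def test_forward_model_identity_single_chromophore(self, table):
        sc = pr.PhantomScene(z_extent_mm=3.0, markers=[])
        sc.body_chromophores = {"HbO2": 2.0}
        sc.skin_chromophores = {"HbO2": 2.0}
        stack = pr.render_pat(sc, table, grid=(60, 60), n_slices=4)
        zz, yy, xx = sc.grid_coords((60, 60), (0.3, 0.1, 0.1), 4)
        body = sc.body_mask_on(zz, yy, xx)
        for vol, lam in zip(stack.volumes, stack.wavelengths_nm):
            expected = 2.0 * table.epsilon_of("HbO2", lam)
            assert np.allclose(vol.data[body], expected)
            assert np.allclose(vol.data[~body], 0.0)

    def test_default_wavelength_tags(self, pat_clean):
        assert pat_clean.wavelengths_nm == [700.0, 730.0, 760.0, 800.0, 850.0]
        assert len(pat_clean) == 5

    def test_missing_wavelength_raises(self, scene, table):
        with pytest.raises(KeyError, match="wavelength"):
            pr.render_pat(scene, table, wavelengths_nm=[999.0])

    @pytest.mark.parametrize("sigma,min_slices,max_slices", [(1.3, 5, 40), (0.0, 1, 3)])
    def test_marker_axial_spread(self, table, sigma, min_slices, max_slices):
        sc = default_scene(seed=3, z_extent_mm=10.0, n_markers=1)
        stack = pr.render_pat(sc, table, marker_axial_sigma_mm=sigma)
        vol = stack.volumes[0]
        m = sc.markers[0]
        my, mx = sc.marker_position_yx(m)
        r0 = int(round(my / 0.1 + 299 / 2))
        c0 = int(round(mx / 0.1 + 299 / 2))
        roi = vol.data[:, r0 - 4:r0 + 5, c0 - 4:c0 + 5].mean(axis=(1, 2))
        bg = np.median(vol.data[:, r0 - 4:r0 + 5, c0 - 4:c0 + 5])
        visible = int((roi > bg + 3 * roi.std() / 3 + 0.1 * roi.max()).sum())
        assert min_slices <= visible <= max_slices

    def test_marker_bright_in_pat_dark_in_mri(self, scene, pat_clean, mri_clean):
        m = scene.markers[0]
        my, mx = scene.marker_position_yx(m)
        k = int(round(m.z_mm / pat_clean.spacing[0]))
        r0 = int(round(my / 0.1 + 299 / 2))
        c0 = int(round(mx / 0.1 + 299 / 2))
        pat_val = pat_clean.volumes[0].data[k, r0, c0]
        assert pat_val > 10 * np.median(pat_clean.volumes[0].data[k])


class TestMasksAndMisalignment:
    def test_mask_nesting_and_self_dice(self, scene):
        body, tumor, core = pr.ground_truth_masks(scene, (120, 120), (0.3, 0.2, 0.2), 20)
        assert pr.dice(body, body) == 1.0
        assert np.all(tumor.data[core.data])
        assert np.all(body.data[tumor.data])

    def test_ellipsoid_volume_matches_analytic(self, scene):
        _, tumor, _ = pr.ground_truth_masks(scene, (250, 250), (0.1, 0.1, 0.1),
                                            int(scene.z_extent_mm / 0.1))
        az, ay, ax = scene.tumor.semi_axes
        analytic = 4.0 / 3.0 * math.pi * az * ay * ax
        assert abs(pr.mask_volume(tumor) - analytic) / analytic < 0.02

    def test_identity_misalignment_is_noop(self, mri_clean):
        model = pr.MisalignmentModel(
            [pr.RigidTransform2D() for _ in range(mri_clean.n_slices)])
        out = pr.apply_misalignment(mri_clean, model)
        assert np.allclose(out.data, mri_clean.data)

    def test_integer_pixel_translation_matches_index_shift(self, mri_clean):
        transforms = [pr.RigidTransform2D() for _ in range(mri_clean.n_slices)]
        transforms[2] = pr.RigidTransform2D(0.0, 0.5, 0.3, (0.0, 0.0))  # 5 px, 3 px
        out = pr.apply_misalignment(mri_clean, pr.MisalignmentModel(transforms))
        assert np.abs(out.data[2, 3:, 5:] - mri_clean.data[2, :-3, :-5]).max() < 1e-9

    def test_transform_count_mismatch_rejected(self, mri_clean):
        with pytest.raises(ValueError, match="per slice"):
            pr.apply_misalignment(mri_clean, pr.MisalignmentModel([pr.RigidTransform2D()]))

    def test_axial_offset_shifts_origin_only(self, mri_clean):
        model = pr.MisalignmentModel(
            [pr.RigidTransform2D() for _ in range(mri_clean.n_slices)],
            axial_offset_mm=1.2)
        out = pr.apply_misalignment(mri_clean, model)
        assert out.origin[0] == mri_clean.origin[0] - 1.2
        assert out.shape == mri_clean.shape

    def test_bounds_enforced(self):
        with pytest.raises(ValueError, match="bounds"):
            pr.MisalignmentModel([pr.RigidTransform2D(0.0, 5.0, 0.0)],
                                 max_translation_mm=3.0)

    def test_random_misalignment_deterministic_and_bounded(self):
        a = pr.random_misalignment(10, seed=5)
        b = pr.random_misalignment(10, seed=5)
        for ta, tb in zip(a.per_slice_transforms, b.per_slice_transforms):
            assert ta == tb
            assert abs(ta.tx) <= 3.0 and abs(ta.theta_deg) <= 10.0


class TestSceneValidation:
    def test_marker_diameter_limit(self):
        with pytest.raises(ValueError, match="marker diameter"):
            pr.PhantomScene(markers=[Marker(5.0, diameter_mm=1.5)])

    def test_organ_containment(self):
        bad = pr.Ellipsoid((5.0, 7.0, 0.0), (2.0, 4.0, 2.0))
        with pytest.raises(ValueError, match="inside the body"):
            pr.PhantomScene(organs=[bad])

    def test_default_marker_spacing_is_10mm(self):
        sc = default_scene(z_extent_mm=30.0)
        zs = [m.z_mm for m in sc.markers]
        assert np.allclose(np.diff(zs), 10.0)
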