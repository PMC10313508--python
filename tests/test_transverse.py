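"""Mutual information metric and the (1+1)-ES rigid/similarity registration."""

import math

import numpy as np
import pytest

import pamreg as pr
from pamreg.transverse import OptimizerParams, mutual_information


def brute_force_mi(a, b, n_bins):
    """Independent double-loop entropy computation (oracle)."""
    def norm_idx(img):
        lo, hi = img.min(), img.max()
        u = np.zeros_like(img, dtype=float) if hi <= lo else (img - lo) / (hi - lo)
        return np.minimum((u * n_bins).astype(int), n_bins - 1)

    ia, ib = norm_idx(np.asarray(a)), norm_idx(np.asarray(b))
    n = ia.size
    joint = np.zeros((n_bins, n_bins))
    for u, v in zip(ia.ravel(), ib.ravel()):
        joint[u, v] += 1
    joint /= n
    ha = hb = hab = 0.0
    for u in range(n_bins):
        pu = joint[u].sum()
        if pu > 0:
            ha -= pu * math.log2(pu)
        pv = joint[:, u].sum()
        if pv > 0:
            hb -= pv * math.log2(pv)
        for v in range(n_bins):
            if joint[u, v] > 0:
                hab -= joint[u, v] * math.log2(joint[u, v])
    return ha + hb - hab


class TestMutualInformation:
    def test_self_mi_of_balanced_binary_image_is_one_bit(self):
        a = np.zeros((16, 16))
        a[:8] = 1.0
        assert mutual_information(a, a, 8) == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_gives_zero(self):
        rng = np.random.default_rng(0)
        assert mutual_information(np.full((10, 10), 3.0), rng.random((10, 10))) == 0.0

    def test_independent_splits_give_zero(self):
        a = np.zeros((16, 16))
        a[:, 8:] = 1.0  # vertical split
        b = np.zeros((16, 16))
        b[8:, :] = 1.0  # horizontal split
        assert mutual_information(a, b, 8) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = rng.random((16, 16))
            b = rng.random((16, 16))
            assert mutual_information(a, b, 8) == pytest.approx(
                brute_force_mi(a, b, 8), abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((12, 12)), rng.random((12, 12))
        assert abs(mutual_information(a, b) - mutual_information(b, a)) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mutual_information(np.zeros((4, 4)), np.zeros((5, 5)))


@pytest.fixture(scope="module")
def slice_pair(preprocessed_pair):
    pat_ref, pat_mask, mri_p, mri_mask = preprocessed_pair
    k = 4
    j = int(round(k / 0.3))
    return (pat_ref.data[j], mri_p.data[k], pat_mask.data[j], mri_mask.data[k],
            (mri_p.origin[1], mri_p.origin[2]))


class TestRegisterSlice:
    def test_already_aligned_pair_stays_near_identity(self, slice_pair):
        pat, mri, _, _, origin = slice_pair
        res = pr.register_slice(pat, mri, "rigid", OptimizerParams(seed=0),
                                (0.1, 0.1), origin)
        t = res.transform
        assert abs(t.tx) < 0.1 and abs(t.ty) < 0.1 and abs(t.theta_deg) < 0.2

    @pytest.mark.parametrize("tx,ty,deg", [(2.0, -1.5, 3.0), (-2.5, 0.8, -8.0)])
    def test_injected_perturbation_recovered(self, slice_pair, tx, ty, deg):
        pat, mri, _, _, origin = slice_pair
        inj = pr.RigidTransform2D(math.radians(deg), tx, ty, (0.0, 0.0))
        moving = pr.apply_transform(mri, inj, (0.1, 0.1), origin)
        res = pr.register_slice(pat, moving, "rigid", OptimizerParams(seed=1),
                                (0.1, 0.1), origin)
        err = res.transform.compose(inj)
        assert abs(err.tx) < 0.2 and abs(err.ty) < 0.2
        assert abs(err.theta_deg) < 0.5

    def test_mi_never_regresses(self, slice_pair):
        pat, mri, _, _, origin = slice_pair
        inj = pr.RigidTransform2D(math.radians(4.0), 1.0, 1.0, (0.0, 0.0))
        moving = pr.apply_transform(mri, inj, (0.1, 0.1), origin)
        res = pr.register_slice(pat, moving, "rigid", OptimizerParams(seed=2),
                                (0.1, 0.1), origin)
        assert res.mi_final >= res.mi_initial

    def test_trace_monotone_nondecreasing(self, slice_pair):
        pat, mri, _, _, origin = slice_pair
        res = pr.register_slice(pat, mri, "rigid", OptimizerParams(seed=3),
                                (0.1, 0.1), origin)
        assert np.all(np.diff(res.mi_trace) >= 0)

    def test_seeded_run_bit_reproducible(self, slice_pair):
        pat, mri, _, _, origin = slice_pair
        r1 = pr.register_slice(pat, mri, "rigid", OptimizerParams(seed=9),
                               (0.1, 0.1), origin)
        r2 = pr.register_slice(pat, mri, "rigid", OptimizerParams(seed=9),
                               (0.1, 0.1), origin)
        assert r1.transform == r2.transform
        assert np.array_equal(r1.registered, r2.registered)

    def test_similarity_model_recovers_scale_free_case(self, slice_pair):
        pat, mri, _, _, origin = slice_pair
        res = pr.register_slice(pat, mri, "similarity", OptimizerParams(seed=4),
                                (0.1, 0.1), origin)
        assert abs(res.transform.scale - 1.0) < 0.02

    def test_degenerate_image_raises(self):
        flat = np.zeros((32, 32))
        with pytest.raises(pr.transverse.RegistrationFailureError):
            pr.register_slice(flat, flat, "rigid",
                              OptimizerParams(seed=0, init="identity"))


class TestOptimizerParams:
    def test_published_defaults(self):
        opt = OptimizerParams()
        assert opt.growth_factor == 1.05
        assert opt.epsilon == 1.5e-6
        assert opt.initial_radius == 6.3e-3
        assert opt.max_iterations == 100

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            OptimizerParams(growth_factor=0.9)
        with pytest.raises(ValueError):
            OptimizerParams(epsilon=1.0, initial_radius=0.5)


class TestVolumeDrivers:
    def test_per_slice_records_cover_pairing(self, preprocessed_pair):
        pat_ref, pat_mask, mri_p, mri_mask = preprocessed_pair
        pairing = pr.align_stacks(pat_ref, mri_p, 0.0)
        opt = OptimizerParams(seed=0, max_iterations=20)
        recs = pr.register_volume_2d(pat_ref, mri_p, pairing, "rigid", opt,
                                     pat_mask.data, mri_mask.data)
        assert len(recs) == mri_p.n_slices
        assert [r.pat_slice for r in recs] == list(pairing)

    def test_volume_3d_near_identity_on_aligned_stacks(self, preprocessed_pair):
        pat_ref, pat_mask, mri_p, mri_mask = preprocessed_pair
        pairing = pr.align_stacks(pat_ref, mri_p, 0.0)
        from pamreg.volume import ImageVolume, Modality
        pat_sub = ImageVolume(pat_ref.data[pairing], mri_p.spacing, mri_p.origin,
                              Modality.PAT)
        res = pr.register_volume_3d(pat_sub, mri_p, "rigid",
                                    OptimizerParams(seed=0, max_iterations=40),
                                    pat_mask=pat_mask.data[pairing],
                                    mri_mask=mri_mask.data)
        d = res.transform.to_dict()
        assert abs(d["tx_mm"]) < 0.3 and abs(d["ty_mm"]) < 0.3
        assert abs(d["rz_deg"]) < 0.5
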