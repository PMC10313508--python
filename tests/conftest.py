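"""Shared fixtures: small phantom scenes rendered once per session."""

import numpy as np
import pytest

import pamreg as pr


@pytest.fixture(scope="session")
def scene():
    """Compact default scene: 8 mm of body, one marker at z = 5 mm."""
    return pr.default_scene(seed=7, z_extent_mm=8.0)


@pytest.fixture(scope="session")
def scene_nomarker():
    return pr.default_scene(seed=7, z_extent_mm=6.0, with_markers=False)


@pytest.fixture(scope="session")
def table():
    return pr.demo_table()


@pytest.fixture(scope="session")
def mri_clean(scene):
    return pr.render_mri(scene, noise_sigma=0.0)


@pytest.fixture(scope="session")
def mri_noisy(scene):
    return pr.render_mri(scene, noise_sigma=2.0)


@pytest.fixture(scope="session")
def pat_clean(scene, table):
    return pr.render_pat(scene, table)


@pytest.fixture(scope="session")
def pat_nomarker(scene_nomarker, table):
    return pr.render_pat(scene_nomarker, table)


@pytest.fixture(scope="session")
def preprocessed_pair(mri_noisy, pat_clean):
    """(pat_ref, pat_mask, mri_p, mri_mask) on the shared 300x300 grid."""
    from pamreg import preprocess as pp
    from pamreg.volume import ImageVolume, Modality

    params = pp.PreprocessParams()
    mri_p, mri_mask = pp.preprocess_mri(mri_noisy, params)
    ref = ImageVolume(np.maximum(pat_clean.as_array(), 0).mean(axis=0),
                      pat_clean.spacing, pat_clean.origin, Modality.PAT)
    pat_ref, pat_mask = pp.preprocess_pat(ref, params)
    return pat_ref, pat_mask, mri_p, mri_mask
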