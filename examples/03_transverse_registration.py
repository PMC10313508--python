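"""Register one perturbed MRI slice onto its PAT partner by maximising MI.

A known rigid motion (2 mm, -1.5 mm, 3 deg) is injected into an MRI slice;
mutual-information registration with the (1+1) evolution strategy recovers
it.  The printed error is the residual after composing the recovered
transform with the injected one (identity = perfect recovery).
"""

import math

import numpy as np

import pamreg as pr
from pamreg import preprocess as pp
from pamreg.volume import ImageVolume, Modality

scene = pr.default_scene(seed=3, z_extent_mm=8.0)
mri = pr.render_mri(scene, noise_sigma=2.0)
pat = pr.render_pat(scene, pr.demo_table())

params = pp.PreprocessParams()
mri_p, mri_mask = pp.preprocess_mri(mri, params)
ref = ImageVolume(np.maximum(pat.as_array(), 0).mean(axis=0), pat.spacing,
                  pat.origin, Modality.PAT)
pat_ref, pat_mask = pp.preprocess_pat(ref, params)

k = 4  # MRI slice, z = 4 mm
j = int(round(k * mri_p.spacing[0] / pat_ref.spacing[0]))
spacing = (0.1, 0.1)
origin = (mri_p.origin[1], mri_p.origin[2])

inj = pr.RigidTransform2D(math.radians(3.0), 2.0, -1.5, (0.0, 0.0))
moving = pr.apply_transform(mri_p.data[k], inj, spacing, origin)
moving_mask = pr.apply_transform(mri_mask.data[k].astype(float), inj,
                                 spacing, origin) > 0.5

res = pr.register_slice(pat_ref.data[j], moving, "rigid",
                        pr.OptimizerParams(seed=0), spacing, origin,
                        pat_mask.data[j], moving_mask)
t = res.transform
err = t.compose(inj)
print(f"injected : tx=2.000 ty=-1.500 theta=3.000 deg")
print(f"recovered: tx={-t.tx:+.3f}* ty={-t.ty:+.3f}* theta={-t.theta_deg:+.3f}* "
      "(*inverse motion)")
print(f"residual : |dtx|={abs(err.tx):.3f} mm |dty|={abs(err.ty):.3f} mm "
      f"|dtheta|={abs(err.theta_deg):.3f} deg")
print(f"MI {res.mi_initial:.3f} -> {res.mi_final:.3f} bits "
      f"in {res.iterations} iterations")
# Residuals of a few hundredths of a mm / deg are typical; the optimiser's
# best-MI trace is monotone because only improvements are accepted.
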