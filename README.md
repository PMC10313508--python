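# pamreg

Co-registration and spectral analysis for **successive photoacoustic
tomography (PAT) + MRI** imaging of small animals.

When the same animal is imaged first in an MR scanner and then in a PAT
scanner on a shared bed, the two stacks disagree in three ways: they are
shifted along the animal's long axis (*z*), each axial slice is slightly
shifted/rotated in-plane by the animal settling during the modality switch,
and the grids differ (MRI 250×250 over 25×25 mm at ~1 mm slices; PAT
300×300 over 30×30 mm at sub-millimetre slices, five illumination
wavelengths). `pamreg` implements the full software chain that fuses them:

1. **Axial registration with skin fiducials.**  Ink markers (< 1 mm,
   spaced 10 mm) are dark in T2 MRI and strong, spectrally flat absorbers in
   PAT, where they smear over ~5 mm of slices.  The marker's mean ROI
   intensity per PAT slice is fitted with a Gaussian
   `a·exp(−(z−μ)²/2σ²)+b`; the peak μ is the marker position, the PAT
   slice nearest μ pairs with the marked MRI slice, and the median offset
   over markers aligns the stacks.
2. **Transverse registration by mutual information.**  For each paired
   slice couple, the rigid (or similarity) in-plane transform maximising
   `MI(A,B) = H(A) + H(B) − H(A,B)` (64-bin joint histogram, bits) is found
   with a (1+1) evolution strategy (growth factor 1.05, minimum search
   radius 1.5·10⁻⁶, initial radius 6.3·10⁻³, 100 iterations), seeded from a
   closed-form centroid/principal-axis alignment.  The PAT slice is the
   fixed image; the MRI slice is resampled.  A whole-volume 3-D variant
   exists for comparison.
3. **Spectral unmixing.**  Per voxel, `p(λ) = Σᵢ cᵢ εᵢ(λ)` is inverted by
   non-negative least squares (or plain LSQ) for HbO₂ / Hb / ICG, giving
   `SO₂ = c_HbO₂ / (c_HbO₂ + c_Hb)` and HbT maps.
4. **Evaluation & fusion.**  Dice overlap of body masks, global-moment SSIM
   (K₁ = 0.01, K₂ = 0.03), Pearson correlation of intensity profiles, ROI
   volumes and time traces; magenta/green overlay rendering and a
   self-contained report bundle.

Because paired in vivo data of this kind is not publicly deposited, the
package ships a **synthetic digital-mouse phantom** (`pamreg.phantom`) that
renders geometrically consistent MRI and multispectral PAT volumes with
known chromophore fields, fiducials, noise, and a known per-slice
misalignment — so every stage can be validated against ground truth.

## Worked example

```python
import pamreg as pr

cfg = pr.PipelineConfig()          # study-condition defaults
cfg.seed = 5
cfg.scene.z_extent_mm = 8.0
result = pr.run_pipeline(cfg)      # simulate -> register -> unmix -> report
```

Output from `examples/05_full_pipeline.py` (this exact run):

```
axial offset recovered: 1.198 mm (injected 1.2)
body-mask DSC, per-slice 2-D rigid: 0.9996 ± 0.0003  (before registration: 0.9567 ± 0.0284)
body-mask DSC, one global 3-D rigid: 0.8491 ± 0.3212
```

The recovered axial offset matches the injected animal-transfer shift to
within half a PAT slice spacing; after per-slice registration the MRI and
PAT body outlines overlap almost perfectly (Dice ≈ 1), while a single
global 3-D rigid transform cannot explain the slice-to-slice jitter and
lands markedly lower — the mechanism behind preferring per-slice 2-D rigid
registration for this kind of data.

The other scripts in `examples/` each exercise one capability (phantom
rendering, marker-based axial alignment, single-slice MI registration,
unmixing/SO₂) and print what the numbers mean.  A thin CLI mirrors the
workflow: `pamreg simulate`, `pamreg pipeline`, `pamreg unmix` with a
YAML/JSON config (schema-validated; unknown keys are rejected).

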