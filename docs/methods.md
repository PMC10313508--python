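# Methods

This note records the models, parameters and design decisions behind
`pamreg`, in the spirit of a package's own methods documentation: what is
computed, under which assumptions, and what the synthetic validation does
and does not demonstrate.

## Coordinate conventions

All arrays are indexed `(z, y, x)` with 0-based, voxel-centred indices;
`z` is the animal's long axis.  `spacing = (dz, dy, dx)` and `origin` are
in millimetres; slice `k` sits at `z₀ + k·dz`.  Transforms act on physical
coordinates, so nothing downstream depends on grid resolution.  NIfTI-1 is
the canonical on-disk format (it carries spacing); multi-page TIFF is
readable with an explicit spacing.  NaNs are rejected at load time rather
than imputed: a NaN that reaches the joint histogram corrupts mutual
information silently, which is far harder to diagnose than an early error.

## The digital mouse phantom

The generator emulates the acquisition geometry of successive small-animal
imaging: MRI as 250×250 pixels over a 25×25 mm field of view with 1.0 mm
slice spacing; PAT as 300×300 pixels over 30×30 mm at five wavelengths
(700/730/760/800/850 nm).  The PAT axial step is configurable with a
0.3 mm default — a typical motorised-stage step, finer than the MRI slice
spacing, which is what makes nearest-slice pairing meaningful.

The scene is an elliptical body cylinder (default semi-axes 8×10 mm)
containing ellipsoidal organs, a tumor with a hypoxic core
(SO₂ = 0.2) inside a perfused rim (SO₂ ≈ 0.74), and thin superficial
vessels.  Ground truth is analytic: masks are rasterised from the same
ellipsoid equations the renderer uses, and the chromophore concentration
fields (HbO₂, Hb, ICG, arbitrary concentration units) are defined per
region.  PAT intensities are generated *only* through the linear
absorption model `p(λ) = Σ cᵢ εᵢ(λ)` — vessels and skin are
hemoglobin-rich regions rather than separate intensity hacks — so a
noiseless render inverts exactly and the unmixing round trip closes to
machine precision.  The single exception is the ink fiducials, which are
rendered as a separate spectrally flat absorber (ink is not one of the
unmixed chromophores); unmixing validation therefore uses marker-free
scenes.

Markers are < 1 mm dots on the skin surface, spaced 10 mm axially.  In MRI
they are hypointense on exactly one slice; in PAT they are bright and
convolved along z with a Gaussian of σ = 1.3 mm, chosen so the visible
spread at typical display thresholds is ≈ 5 mm — the behaviour that makes
naive argmax slice-picking unreliable and motivates the Gaussian fit.

Misalignment is drawn as a global in-plane rigid motion (default up to
2 mm / 5°) plus independent per-slice jitter (σ 0.4 mm / 1°), both clipped
to |t| ≤ 3 mm, |θ| ≤ 10°, plus a global axial offset (default 1.2 mm)
realised as a z-origin shift.  The split matters: the global part is what a
single 3-D rigid fit can undo, the jitter is what only per-slice 2-D
registration can undo, and the comparison between the two reproduces the
observed superiority of per-slice registration mechanistically.  The
magnitude bounds are a modelling choice (the motion of a bedded,
anaesthetised animal is subtle but not quantified); they are configurable.

Noise is additive Gaussian in both modalities (a Rician MRI option was
considered and deferred; at the SNRs used the difference is immaterial for
registration and unmixing behaviour).  All randomness flows through
NumPy's PCG64 generator seeded from the scene/config, so every render and
every pipeline run is bit-reproducible.

What the phantom does *not* emulate: acoustic propagation and
reconstruction artefacts, light-fluence inhomogeneity (so PAT intensities
are linear in absorption by construction), breathing motion, deformable
anatomy, and realistic texture.  Passing tests therefore demonstrate the
correctness of the *algorithms* under the stated motion/noise model, not
performance on in vivo data.

## Preprocessing

Fixed order: denoise → (PAT only: clip negatives) → segment → resize.

* **Wiener denoising** is the classic pixelwise adaptive form: local mean
  and variance over an odd window (default 3×3, the smallest adaptive
  neighbourhood), noise variance estimated as the mean of the local
  variances.  It is implemented directly with reflected boundaries because
  the zero-padded boundary handling in off-the-shelf routines biases edge
  pixels and breaks the "constant image in → constant image out" contract.
* **Body segmentation** replaces interactive delineation with a
  reproducible chain: per-slice Otsu threshold → largest connected
  component → morphological closing (radius 2 px) → hole filling.  The
  Otsu threshold is computed on intensities clipped at the 99.5th
  percentile so that a 50-pixel ink marker cannot hijack the
  background/tissue split; percentile clipping commutes with affine
  intensity rescaling, preserving Otsu's invariance.  Externally supplied
  masks can be substituted.
* **FOV matching** embeds each MRI slice centred in the 30×30 mm PAT field
  of view (background value 0) at its own pixel size and resamples to
  300×300 — with the default 0.1 mm pixels this is pure padding and
  exactly preserves physical scale.

## Axial registration

The marker profile (mean intensity in a user-stated circular ROI, per PAT
slice in a ±6 mm window around the expected position) is fitted with
`a·exp(−(z−μ)²/2σ²) + b` by Levenberg–Marquardt least squares,
moment-initialised (μ₀ = intensity-weighted centroid, σ₀ = weighted std,
a₀ = range, b₀ = min).  The additive baseline b is included because PAT
tissue background under the marker is nonzero; without it the peak
estimate is biased toward the stack centre.  The fitted mean is invariant
to affine intensity transforms of the profile.

Offsets from multiple markers are combined by the **median** — robust to a
single bad fit, which is the realistic failure mode.  Slice pairing is
nearest-neighbour in physical z after offset correction; ties break to the
lower index, and monotonicity of the pairing follows from sorted
positions.  On the noiseless phantom the offset is recovered to within
half the PAT slice spacing (the information-theoretic limit of
nearest-slice matching); at profile SNR 10 the matched slice stays within
±1 slice.

## Transverse (in-plane) registration

Mutual information is computed from a 64-bin joint histogram over the full
common grid (background included), each image min–max normalised, with
entropies in bits (`0·log 0 ≡ 0`) — base 2 makes `MI(A,A)` of a balanced
binary image exactly 1 bit, a convenient exactness anchor.  The estimator
matches a brute-force double-loop implementation to 1e−10 and is symmetric
to 1e−12.

The optimiser is a (1+1) evolution strategy in a normalised parameter
space (1 unit = 1 mm translation, 1° rotation, 0.01 scale): perturb the
current parameters by `radius × random unit direction`, accept on MI
improvement (radius × 1.05), reject otherwise (radius × 1.05^−0.25), stop
after 100 iterations or when the radius falls below 1.5·10⁻⁶.  The
asymmetric contraction (¼ exponent) is the classic adaptive-step rule for
this optimiser family; a symmetric divide makes the radius a zero-drift
random walk that can never grow out of the small initial radius
(6.3·10⁻³) within the iteration budget, stalling the search — with the
asymmetric rule the radius expands geometrically at ordinary acceptance
rates.

A local search of this radius cannot by itself traverse a 3 mm / 10°
misalignment, so registration is **seeded from a closed-form moment
alignment**: centroids and principal axes of the two foreground masks
(body masks when available, percentile-clipped Otsu foregrounds
otherwise) give an initial rigid guess, which the ES then refines on the
MI objective.  The principal-axis angle is taken modulo π with the
representative nearest zero — correct for the < 90° motions at hand.  The
identity is always retained as a second start and the best final MI wins,
so the returned MI can never fall below the unregistered value and the
best-MI trace is monotone.  Optional restarts jitter the initial guess.
One practical caveat: if a caller passes a foreground mask that does not
correspond to the moving image actually being registered, the moment seed
is meaningless; the pipeline always derives both masks from the images it
registers.

On phantom slice pairs with injected perturbations (|t| ≤ 3 mm,
|θ| ≤ 10°) the median recovery error is ~0.005 mm and ~0.02°, and the
post-registration body-mask Dice exceeds 0.99 on every pair.

The 3-D variant estimates one global 6-parameter rigid (or 7-parameter
similarity) transform over the volumetric joint histogram, same optimiser,
metric evaluated on an in-plane 2× subsampled view for speed and applied
at full resolution.  It recovers purely global misalignments to
< 0.1 mm / 0.1°, and on jittered phantoms its mean Dice falls well below
the per-slice result — the ordering the method comparison is designed to
expose.

## Unmixing

Per-voxel solve of `p = E c` with `E` the wavelengths × chromophores
extinction matrix.  Default solver is NNLS (concentrations are physical);
implementation detail: the unconstrained least-squares solution is
computed for all voxels in one vectorised call and only voxels violating
non-negativity are re-solved with NNLS, which on realistic data is a small
minority.  Plain LSQ is retained for comparison; per voxel its residual is
never above the NNLS residual.  Rank deficiency raises an error naming the
most collinear chromophore pair.  `SO₂ = c_HbO₂/(c_HbO₂+c_Hb)` is reported
only where HbT exceeds a threshold (default 10⁻⁶ × max HbT — guards 0/0
without masking real signal); excluded voxels carry an explicit validity
flag, never a silent zero.

Two extinction tables ship with the package: a bundled Hb/HbO₂/ICG CSV
compiled from standard literature tabulations (reference data for use on
real acquisitions), and a synthetic well-conditioned `demo_table()` used by
the phantom and tests — algorithm validation deliberately does not depend
on literature spectral values.

## Evaluation metrics

* **Dice**: `2|X∩Y|/(|X|+|Y|)`; two empty masks score 1 with a warning
  (the 0/0 convention is made explicit rather than implicit).
* **SSIM** is the *global-moment* single-value form (whole-image means,
  variances, covariance; C₁=(K₁L)², C₂=(K₂L)², K₁=0.01, K₂=0.03), not the
  sliding-window mean; a windowed variant is available behind a flag.  L
  defaults to the reference image's max−min.  In the pipeline's
  cross-modality comparison both slices are min–max normalised (L=1)
  first, since the two modalities' native intensity scales are unrelated.
* **Pearson profile correlation** bilinearly samples both images along a
  physical line at a stated step and correlates the two vectors;
  zero-variance profiles are an error, not a 0.

All four match independent brute-force implementations to 1e−10 on random
small inputs.

## Problem sizes and runtimes

The default pipeline configuration uses a 12 mm body extent (12 MRI
slices, 41 PAT slices at 0.3 mm) — long enough to hold one full marker
spread and a tumor, small enough that the full pipeline (registration of
every slice plus unmixing of 5×41×300×300 voxels) completes in well under
a minute on one CPU.  The acceptance script's method comparison and
20-pair recovery experiment use 8–12 mm scenes for the same reason; sizes
are configuration, not algorithmic limits.

## Known limitations

* Rigid/similarity in-plane motion only; no deformable model, no breathing
  correction.
* MI is the plain histogram estimator; no Parzen windowing or analytic
  gradients.
* Fluence is assumed uniform, so unmixing on real PAT data inherits
  spectral-colouring bias that the phantom cannot reveal.
* The global-moment SSIM saturates near 1 for images dominated by shared
  background; it is reported for fidelity to the evaluation convention,
  with Dice carrying the discriminative weight.
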