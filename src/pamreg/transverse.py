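"""In-plane mutual-information registration of MRI slices to PAT slices.

Each axially paired slice couple is registered by maximising the mutual
information

    MI(A, B) = H(A) + H(B) - H(A, B)

(entropies in bits from a joint intensity histogram) over a rigid —
optionally similarity — in-plane transform.  The PAT slice is the fixed
(reference) image and the MRI slice the moving image; the recovered
transform is applied to the MRI.  The optimiser is a (1+1) evolution
strategy in a normalised parameter space: a perturbation of the current
parameters is drawn inside the current search radius, accepted if it
improves MI (whereupon the radius grows by the growth factor), and rejected
otherwise (the radius contracts); iteration stops after ``max_iterations``
or once the radius falls below its minimum size.

Because the capture range of a small-radius local search is limited, the
optimiser is seeded from a closed-form moment (centroid + principal-axis)
alignment of the two foreground masks by default, and can be restarted from
jittered initialisations; both behaviours are controlled by
:class:`OptimizerParams`.

The whole-volume 3-D variant — a single rigid/similarity transform for the
entire stack, used to quantify how much per-slice registration buys — runs
the same metric and optimiser over the volumetric joint histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import filters

from .transforms import (RigidTransform2D, RigidTransform3D, SimilarityTransform2D,
                         apply_transform, apply_transform_3d, image_center_mm)
from .volume import ImageVolume


class RegistrationFailureError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Mutual information


def _normalize01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float64)
    return (img - lo) / (hi - lo)


def _bin_indices(img: np.ndarray, n_bins: int) -> np.ndarray:
    return np.minimum((_normalize01(img) * n_bins).astype(np.intp), n_bins - 1)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(a: np.ndarray, b: np.ndarray, n_bins: int = 64) -> float:
    """MI in bits between two equal-shape images, from a joint histogram.

    Intensities are min–max normalised per image into ``n_bins`` equal bins
    over the full grid (background included); ``0·log 0`` is taken as 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty images")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ia = _bin_indices(a, n_bins)
    ib = _bin_indices(b, n_bins)
    joint = np.bincount(ia.ravel() * n_bins + ib.ravel(),
                        minlength=n_bins * n_bins).astype(np.float64)
    joint /= joint.sum()
    pj = joint.reshape(n_bins, n_bins)
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    return _entropy_bits(pa) + _entropy_bits(pb) - _entropy_bits(joint)


# ---------------------------------------------------------------------------
# Optimiser


@dataclass
class OptimizerParams:
    """(1+1) evolution-strategy settings.

    ``growth_factor``, ``epsilon`` (minimum search radius), ``initial_radius``
    and ``max_iterations`` default to the published operating point
    (1.05, 1.5e-6, 6.3e-3, 100).  ``shrink_exponent`` sets how the radius
    contracts on rejection (``radius *= growth_factor ** -shrink_exponent``);
    the asymmetric default 0.25 keeps the radius growing at typical
    acceptance rates, the classic adaptive rule for this optimiser family.
    ``parameter_scales`` converts one search-space unit into physical units
    per parameter: (mm, mm, rad[, scale]) for (tx, ty, theta[, s]).
    """

    growth_factor: float = 1.05
    epsilon: float = 1.5e-6
    initial_radius: float = 6.3e-3
    max_iterations: int = 100
    seed: int = 0
    shrink_exponent: float = 0.25
    n_bins: int = 64
    n_starts: int = 1
    init: str = "moments"  # or "identity"
    translation_scale_mm: float = 1.0
    rotation_scale_rad: float = math.radians(1.0)
    scale_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.growth_factor <= 1:
            raise ValueError("growth_factor must be > 1")
        if not (0 < self.epsilon < self.initial_radius):
            raise ValueError("require 0 < epsilon < initial_radius")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.init not in ("moments", "identity"):
            raise ValueError(f"unknown init {self.init!r}")


def _one_plus_one_es(objective, x0: np.ndarray, opt: OptimizerParams,
                     rng: np.random.Generator) -> tuple[np.ndarray, list[float], int]:
    """Maximise ``objective`` from ``x0``; returns (best x, best-MI trace, iters)."""
    x = np.asarray(x0, dtype=float)
    f = objective(x)
    if not np.isfinite(f):
        raise RegistrationFailureError("non-finite similarity metric at initialisation")
    radius = opt.initial_radius
    grow = opt.growth_factor
    shrink = opt.growth_factor ** (-opt.shrink_exponent)
    trace = [f]
    it = 0
    for it in range(1, opt.max_iterations + 1):
        d = rng.normal(size=x.shape)
        n = np.linalg.norm(d)
        if n == 0:
            continue
        cand = x + radius * d / n
        fc = objective(cand)
        if np.isfinite(fc) and fc > f:
            x, f = cand, fc
            radius *= grow
        else:
            radius *= shrink
        trace.append(f)
        if radius < opt.epsilon:
            break
    return x, trace, it


# ---------------------------------------------------------------------------
# Moment-based initialisation


def _foreground(img: np.ndarray) -> np.ndarray:
    if img.max() <= img.min():
        return np.ones(img.shape, dtype=bool)
    # clip sparse ultra-bright pixels (fiducial ink) so Otsu separates
    # background from tissue rather than tissue from marker
    clipped = np.minimum(img, np.percentile(img, 99.5))
    if clipped.max() <= clipped.min():
        return np.ones(img.shape, dtype=bool)
    return clipped > filters.threshold_otsu(clipped)


def _mask_moments(mask: np.ndarray, spacing: tuple[float, float],
                  origin: tuple[float, float]) -> tuple[np.ndarray, float]:
    """Centroid (x, y) mm and principal-axis angle of a boolean mask."""
    dy, dx = spacing
    y0, x0 = origin
    rr, cc = np.nonzero(mask)
    if len(rr) == 0:
        return np.array([0.0, 0.0]), 0.0
    ys = y0 + rr * dy
    xs = x0 + cc * dx
    cy, cx = ys.mean(), xs.mean()
    yc, xc = ys - cy, xs - cx
    cov = np.array([[np.mean(xc * xc), np.mean(xc * yc)],
                    [np.mean(xc * yc), np.mean(yc * yc)]])
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    angle = math.atan2(v[1], v[0])
    return np.array([cx, cy]), angle


def moments_init(fixed: np.ndarray, moving: np.ndarray,
                 spacing: tuple[float, float], origin: tuple[float, float],
                 center: tuple[float, float],
                 fixed_mask: np.ndarray | None = None,
                 moving_mask: np.ndarray | None = None) -> RigidTransform2D:
    """Closed-form rigid guess aligning foreground centroids and principal axes.

    The principal-axis angle is defined modulo pi; the representative
    nearest zero is chosen, which is correct for the modest (|theta| well
    below 90 deg) motions a bedded animal undergoes between modalities.
    """
    fm = fixed_mask if fixed_mask is not None else _foreground(fixed)
    mm = moving_mask if moving_mask is not None else _foreground(moving)
    c_f, a_f = _mask_moments(fm, spacing, origin)
    c_m, a_m = _mask_moments(mm, spacing, origin)
    dtheta = a_f - a_m
    while dtheta > math.pi / 2:
        dtheta -= math.pi
    while dtheta <= -math.pi / 2:
        dtheta += math.pi
    guess = RigidTransform2D(dtheta, 0.0, 0.0, center)
    mapped = guess.apply_points(c_m[None, :])[0]
    t = c_f - mapped
    return RigidTransform2D(dtheta, float(t[0]), float(t[1]), center)


# ---------------------------------------------------------------------------
# Slice registration


@dataclass
class RegistrationResult:
    transform: RigidTransform2D
    registered: np.ndarray
    mi_trace: list[float]
    mi_initial: float
    mi_final: float
    iterations: int


def _params_to_transform(x: np.ndarray, model: str, opt: OptimizerParams,
                         center: tuple[float, float]) -> RigidTransform2D:
    tx = x[0] * opt.translation_scale_mm
    ty = x[1] * opt.translation_scale_mm
    th = x[2] * opt.rotation_scale_rad
    if model == "similarity":
        s = 1.0 + x[3] * opt.scale_scale
        if s <= 0.05:
            s = 0.05
        return SimilarityTransform2D(th, tx, ty, center, s)
    return RigidTransform2D(th, tx, ty, center)


def _transform_to_params(t: RigidTransform2D, model: str, opt: OptimizerParams) -> np.ndarray:
    x = [t.tx / opt.translation_scale_mm, t.ty / opt.translation_scale_mm,
         t.theta / opt.rotation_scale_rad]
    if model == "similarity":
        x.append((t.scale - 1.0) / opt.scale_scale)
    return np.asarray(x, dtype=float)


def register_slice(fixed_pat: np.ndarray, moving_mri: np.ndarray,
                   model: str = "rigid",
                   opt: OptimizerParams | None = None,
                   spacing: tuple[float, float] = (0.1, 0.1),
                   origin: tuple[float, float] | None = None,
                   fixed_mask: np.ndarray | None = None,
                   moving_mask: np.ndarray | None = None,
                   fill: float = 0.0) -> RegistrationResult:
    """Register one MRI slice (moving) onto its PAT partner (fixed).

    Both slices must live on the same grid (use the preprocess module
    first).  Deterministic for a fixed ``opt.seed``.
    """
    if model not in ("rigid", "similarity"):
        raise ValueError(f"unknown model {model!r}")
    opt = opt or OptimizerParams()
    fixed_pat = np.asarray(fixed_pat, dtype=np.float64)
    moving_mri = np.asarray(moving_mri, dtype=np.float64)
    if fixed_pat.shape != moving_mri.shape:
        raise ValueError("fixed and moving slices must share a grid")
    if fixed_pat.max() <= fixed_pat.min() or moving_mri.max() <= moving_mri.min():
        raise RegistrationFailureError("degenerate (constant) image: nothing to register")
    h, w = fixed_pat.shape
    dy, dx = spacing
    if origin is None:
        origin = (-(h - 1) / 2.0 * dy, -(w - 1) / 2.0 * dx)
    center = image_center_mm((h, w), spacing, origin)
    mi0 = mutual_information(fixed_pat, moving_mri, opt.n_bins)
    if not np.isfinite(mi0):
        raise RegistrationFailureError("degenerate images: non-finite MI")

    def objective(x: np.ndarray) -> float:
        t = _params_to_transform(x, model, opt, center)
        warped = apply_transform(moving_mri, t, spacing, origin, fill)
        return mutual_information(fixed_pat, warped, opt.n_bins)

    n_par = 4 if model == "similarity" else 3
    # identity is always a candidate start: the elitist search then can never
    # end below the unregistered MI, whatever the moment guess does
    inits: list[np.ndarray] = [np.zeros(n_par)]
    if opt.init == "moments":
        guess = moments_init(fixed_pat, moving_mri, spacing, origin, center,
                             fixed_mask, moving_mask)
        inits.insert(0, _transform_to_params(guess, model, opt))
    rng_starts = np.random.default_rng((opt.seed, 17))
    while len(inits) < max(1, opt.n_starts):  # extra restarts jitter the first guess
        inits.append(inits[0] + rng_starts.normal(0.0, 0.5, n_par))
    best_x, best_f, best_trace, best_it = inits[0], -np.inf, [], 0
    for si, x0 in enumerate(inits):
        rng = np.random.default_rng((opt.seed, si))
        x, trace, it = _one_plus_one_es(objective, x0, opt, rng)
        f = trace[-1]
        if f > best_f:
            best_x, best_f, best_trace, best_it = x, f, trace, it
    t = _params_to_transform(best_x, model, opt, center)
    registered = apply_transform(moving_mri, t, spacing, origin, fill)
    return RegistrationResult(t, registered, best_trace, mi0, best_f, best_it)


# ---------------------------------------------------------------------------
# Volume-level drivers


@dataclass
class SliceRegistrationRecord:
    mri_slice: int
    pat_slice: int
    result: RegistrationResult


def register_volume_2d(pat: ImageVolume, mri: ImageVolume, pairing: np.ndarray,
                       model: str = "rigid", opt: OptimizerParams | None = None,
                       pat_mask: np.ndarray | None = None,
                       mri_mask: np.ndarray | None = None
                       ) -> list[SliceRegistrationRecord]:
    """Independent per-slice registration of every paired slice couple.

    ``pairing[k]`` is the PAT slice index for MRI slice ``k`` (from the
    axial stage).  A slice whose registration fails is recorded with its
    exception logged and skipped, never fatal for the run.
    """
    opt = opt or OptimizerParams()
    if pat.data.shape[1:] != mri.data.shape[1:]:
        raise ValueError("PAT and MRI must share the in-plane grid; preprocess first")
    dy, dx = mri.spacing[1], mri.spacing[2]
    origin = (mri.origin[1], mri.origin[2])
    records = []
    for k, j in enumerate(np.asarray(pairing, dtype=int)):
        res = register_slice(
            pat.data[j], mri.data[k], model,
            replace(opt, seed=opt.seed * 100003 + k),
            (dy, dx), origin,
            None if pat_mask is None else pat_mask[j],
            None if mri_mask is None else mri_mask[k])
        records.append(SliceRegistrationRecord(k, int(j), res))
    return records


def registered_volume(mri: ImageVolume, records: list[SliceRegistrationRecord]
                      ) -> ImageVolume:
    """Assemble the per-slice registered images back into a volume."""
    out = mri.data.astype(np.float64).copy()
    for rec in records:
        out[rec.mri_slice] = rec.result.registered
    return mri.copy_with(data=out)


@dataclass
class VolumeRegistrationResult:
    transform: RigidTransform3D
    registered: ImageVolume
    mi_trace: list[float]
    mi_initial: float
    mi_final: float
    iterations: int


def register_volume_3d(pat: ImageVolume, mri: ImageVolume, model: str = "rigid",
                       opt: OptimizerParams | None = None,
                       downsample: int = 2,
                       pat_mask: np.ndarray | None = None,
                       mri_mask: np.ndarray | None = None) -> VolumeRegistrationResult:
    """One global 3-D rigid (or similarity) transform for the whole stack.

    The volumes must share a grid (resample the MRI axially onto the PAT
    slice positions first, e.g. with the axial pairing).  The metric is
    evaluated on an in-plane ``downsample``-strided view for speed; the
    final transform is applied at full resolution.
    """
    if model not in ("rigid", "similarity"):
        raise ValueError(f"unknown model {model!r}")
    opt = opt or OptimizerParams()
    if pat.shape != mri.shape:
        raise ValueError("volumes must share a grid for 3-D registration")
    spacing = mri.spacing
    origin = mri.origin
    nz, ny, nx = mri.shape
    center = (origin[2] + (nx - 1) / 2.0 * spacing[2],
              origin[1] + (ny - 1) / 2.0 * spacing[1],
              origin[0] + (nz - 1) / 2.0 * spacing[0])
    ds = max(1, int(downsample))
    pat_s = pat.data[:, ::ds, ::ds]
    mov_s = mri.data[:, ::ds, ::ds]
    sp_s = (spacing[0], spacing[1] * ds, spacing[2] * ds)
    mi0 = mutual_information(pat_s, mov_s, opt.n_bins)

    tsc, rsc, ssc = opt.translation_scale_mm, opt.rotation_scale_rad, opt.scale_scale
    n_par = 7 if model == "similarity" else 6

    def to_transform(x: np.ndarray) -> RigidTransform3D:
        s = 1.0 + x[6] * ssc if model == "similarity" else 1.0
        return RigidTransform3D(rx=x[3] * rsc, ry=x[4] * rsc, rz=x[5] * rsc,
                                tx=x[0] * tsc, ty=x[1] * tsc, tz=x[2] * tsc,
                                center=center, s=max(s, 0.05))

    def objective(x: np.ndarray) -> float:
        warped = apply_transform_3d(mov_s, to_transform(x), sp_s, origin)
        return mutual_information(pat_s, warped, opt.n_bins)

    inits = [np.zeros(n_par)]
    if opt.init == "moments":
        # centroid alignment + in-plane principal axis on the mid-slice
        guess = moments_init(pat.data[nz // 2], mri.data[nz // 2],
                             (spacing[1], spacing[2]), (origin[1], origin[2]),
                             (center[0], center[1]),
                             None if pat_mask is None else pat_mask[nz // 2],
                             None if mri_mask is None else mri_mask[nz // 2])
        x0 = np.zeros(n_par)
        x0[0] = guess.tx / tsc
        x0[1] = guess.ty / tsc
        x0[5] = guess.theta / rsc
        inits.insert(0, x0)
    best = None
    for si, x0 in enumerate(inits):
        rng = np.random.default_rng((opt.seed, 3, si))
        x, trace, it = _one_plus_one_es(objective, x0, opt, rng)
        if best is None or trace[-1] > best[1][-1]:
            best = (x, trace, it)
    x, trace, it = best
    t = to_transform(x)
    registered = mri.copy_with(data=apply_transform_3d(mri.data, t, spacing, origin))
    return VolumeRegistrationResult(t, registered, trace, mi0, trace[-1], it)
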