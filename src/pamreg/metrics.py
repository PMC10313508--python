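"""Quantitative evaluation: Dice overlap, global-statistics SSIM, Pearson
profile correlation, mask volumes and ROI time traces.

The SSIM here is the *global-moment* form — one value per image pair from
whole-image means, variances and covariance,

    SSIM = (2 mu_I mu_x + C1)(2 sigma_Ix + C2)
           / ((mu_I^2 + mu_x^2 + C1)(sigma_I^2 + sigma_x^2 + C2)),

with C1 = (K1 L)^2, C2 = (K2 L)^2 and K1 = 0.01, K2 = 0.03 — not the
sliding-window local mean most libraries compute.  A windowed variant is
available behind a flag for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ImageVolume


@dataclass
class SSIMParams:
    K1: float = 0.01
    K2: float = 0.03
    L: float | None = None  # None: max-min of the reference image

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("K1 and K2 must be > 0")
        if self.L is not None and self.L <= 0:
            raise ValueError("dynamic range L must be > 0")


@dataclass
class ProfileLine:
    """A sampling line between two in-plane physical points (mm)."""

    start_mm: tuple[float, float]  # (y, x)
    end_mm: tuple[float, float]
    step_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("sampling step must be > 0")
        if np.allclose(self.start_mm, self.end_mm):
            raise ValueError("profile endpoints must be distinct")

    def sample_points(self) -> np.ndarray:
        p0 = np.asarray(self.start_mm, dtype=float)
        p1 = np.asarray(self.end_mm, dtype=float)
        length = float(np.linalg.norm(p1 - p0))
        n = max(int(np.floor(length / self.step_mm)) + 1, 2)
        ts = np.linspace(0.0, 1.0, n)
        return p0[None, :] + ts[:, None] * (p1 - p0)[None, :]


def dice(x: BinaryMask | np.ndarray, y: BinaryMask | np.ndarray) -> float:
    """Dice similarity coefficient 2|X∩Y| / (|X|+|Y|) of two binary masks.

    Two empty masks score 1 (vacuous perfect agreement; a warning is
    emitted because the 0/0 case is a convention, not a measurement).
    """
    xa = x.data if isinstance(x, BinaryMask) else np.asarray(x).astype(bool)
    ya = y.data if isinstance(y, BinaryMask) else np.asarray(y).astype(bool)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    nx, ny_ = int(xa.sum()), int(ya.sum())
    if nx + ny_ == 0:
        warnings.warn("dice of two empty masks defined as 1 (vacuous agreement)")
        return 1.0
    inter = int(np.logical_and(xa, ya).sum())
    return 2.0 * inter / (nx + ny_)


def ssim_global(reference: np.ndarray, test: np.ndarray,
                params: SSIMParams | None = None) -> float:
    """Single global SSIM value from whole-image first and second moments."""
    params = params or SSIMParams()
    I = np.asarray(reference, dtype=np.float64)
    x = np.asarray(test, dtype=np.float64)
    if I.shape != x.shape:
        raise ValueError(f"shape mismatch: {I.shape} vs {x.shape}")
    L = params.L if params.L is not None else float(I.max() - I.min())
    if L <= 0:
        L = 1.0  # constant reference: fall back to unit range
    C1 = (params.K1 * L) ** 2
    C2 = (params.K2 * L) ** 2
    mu_i, mu_x = I.mean(), x.mean()
    var_i, var_x = I.var(), x.var()
    cov = ((I - mu_i) * (x - mu_x)).mean()
    return float((2 * mu_i * mu_x + C1) * (2 * cov + C2)
                 / ((mu_i ** 2 + mu_x ** 2 + C1) * (var_i + var_x + C2)))


def ssim_windowed(reference: np.ndarray, test: np.ndarray,
                  params: SSIMParams | None = None, win_size: int = 7) -> float:
    """Conventional sliding-window SSIM (mean over local windows), for
    comparison with the global-moment form."""
    from skimage.metrics import structural_similarity

    params = params or SSIMParams()
    I = np.asarray(reference, dtype=np.float64)
    x = np.asarray(test, dtype=np.float64)
    L = params.L if params.L is not None else float(I.max() - I.min())
    return float(structural_similarity(I, x, data_range=L if L > 0 else 1.0,
                                       K1=params.K1, K2=params.K2,
                                       win_size=win_size, gaussian_weights=False))


def sample_profile(img: np.ndarray, line: ProfileLine,
                   spacing: tuple[float, float] = (0.1, 0.1),
                   origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Bilinear samples of a 2-D image along a physical line."""
    pts = line.sample_points()  # (n, 2) as (y, x) mm
    dy, dx = spacing
    y0, x0 = origin
    rows = (pts[:, 0] - y0) / dy
    cols = (pts[:, 1] - x0) / dx
    h, w = img.shape
    if rows.min() < -0.5 or rows.max() > h - 0.5 or cols.min() < -0.5 or cols.max() > w - 0.5:
        raise ValueError("profile line leaves the image bounds")
    return ndimage.map_coordinates(np.asarray(img, dtype=np.float64),
                                   [rows, cols], order=1, mode="nearest")


def pearson_profile(img_a: np.ndarray, img_b: np.ndarray, line: ProfileLine,
                    spacing: tuple[float, float] = (0.1, 0.1),
                    origin: tuple[float, float] = (0.0, 0.0)) -> float:
    """Pearson correlation of the two images' intensity profiles along a line."""
    pa = sample_profile(img_a, line, spacing, origin)
    pb = sample_profile(img_b, line, spacing, origin)
    if len(pa) < 3:
        raise ValueError("need at least 3 profile samples")
    if pa.std() == 0 or pb.std() == 0:
        raise ValueError("zero-variance profile: correlation undefined")
    return float(np.corrcoef(pa, pb)[0, 1])


def mask_volume(mask: BinaryMask) -> float:
    """Physical volume of a mask in mm^3 (voxel count x voxel volume)."""
    dz, dy, dx = mask.spacing
    return float(mask.data.sum()) * dz * dy * dx


def roi_timetrace(series: list[ImageVolume], roi: BinaryMask
                  ) -> list[tuple[int, float, float]]:
    """ROI mean per time point and percent change from the first time point.

    Returns ``[(t_index, mean, percent_change_from_baseline), ...]``; the
    convention matches reporting a +39.12% peak as ``39.12``.
    """
    if not roi.data.any():
        raise ValueError("empty ROI")
    shape = series[0].shape
    for v in series:
        if v.shape != shape:
            raise ValueError("all volumes in the series must share a grid")
    if roi.shape != shape:
        raise ValueError("ROI grid must match the series grid")
    out = []
    baseline = None
    for t, vol in enumerate(series):
        m = float(vol.data[roi.data].mean())
        if baseline is None:
            baseline = m
        pct = 0.0 if baseline == 0 else (m - baseline) / baseline * 100.0
        out.append((t, m, pct))
    return out
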