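"""Axial (long-axis) alignment of PAT and MRI stacks via surface ink markers.

An ink fiducial occupies a single MRI slice but, because of the poorer PAT
elevational resolution, smears across several millimetres of PAT slices.
The marker's true axial position is therefore recovered by (1) measuring the
mean intensity inside a small marker ROI on every PAT slice, (2) fitting a
Gaussian (with additive baseline) to that intensity-vs-z curve, and
(3) taking the fitted peak as the marker position.  The PAT slice nearest
the peak is declared the partner of the marked MRI slice; with several
markers the per-marker offsets are combined by their median, and the
remaining slices are paired by nearest physical position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .volume import ImageVolume, MultispectralStack


@dataclass
class MarkerROI:
    """Circular in-plane region believed to contain the marker."""

    center_px: tuple[float, float]  # (row, col)
    radius_px: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        r0, c0 = self.center_px
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius_px ** 2


@dataclass
class MarkerProfile:
    """Per-slice mean marker-ROI intensity along z."""

    slice_positions_mm: np.ndarray
    mean_intensity: np.ndarray
    roi: MarkerROI

    def __post_init__(self) -> None:
        self.slice_positions_mm = np.asarray(self.slice_positions_mm, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.slice_positions_mm.shape != self.mean_intensity.shape:
            raise ValueError("positions and intensities must have equal length")
        if np.any(np.diff(self.slice_positions_mm) <= 0):
            raise ValueError("slice positions must be strictly increasing")


@dataclass
class GaussianFit:
    """a * exp(-(z - mu)^2 / (2 sigma^2)) + b fitted to a marker profile."""

    amplitude: float
    mean_mm: float
    sigma_mm: float
    offset: float
    rmse: float

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError("sigma must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((z - self.mean_mm) / self.sigma_mm) ** 2) \
            + self.offset


class FitFailureError(RuntimeError):
    """Gaussian fit did not converge; carries the best iterate."""

    def __init__(self, message: str, best: GaussianFit | None = None) -> None:
        super().__init__(message)
        self.best = best


def extract_marker_profile(stack: ImageVolume | MultispectralStack, roi: MarkerROI,
                           z_range_mm: tuple[float, float] | None = None) -> MarkerProfile:
    """Mean ROI intensity per slice within ``z_range_mm`` (inclusive).

    For a multispectral stack the wavelength volumes are averaged first (the
    ink absorbs broadly, so averaging only improves SNR).
    """
    if isinstance(stack, MultispectralStack):
        data = stack.as_array().mean(axis=0)
        vol = stack.volumes[0]
    else:
        data = stack.data
        vol = stack
    h, w = data.shape[1:]
    r0, c0 = roi.center_px
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("marker ROI centre outside image bounds")
    positions = vol.origin[0] + np.arange(data.shape[0]) * vol.spacing[0]
    if z_range_mm is not None:
        lo, hi = z_range_mm
        if hi <= lo:
            raise ValueError("empty z range")
        sel = (positions >= lo) & (positions <= hi)
        if not sel.any():
            raise ValueError("z range selects no slices")
    else:
        sel = np.ones(len(positions), dtype=bool)
    m = roi.mask((h, w))
    means = data[sel][:, m].mean(axis=1)
    return MarkerProfile(positions[sel], means, roi)


def _gauss(z, a, mu, sigma, b):
    return a * np.exp(-0.5 * ((z - mu) / sigma) ** 2) + b


def fit_gaussian(profile: MarkerProfile, max_iterations: int = 2000) -> GaussianFit:
    """Least-squares Gaussian+offset fit, moment-initialised.

    Initialisation: mu from the intensity-weighted centroid, sigma from the
    weighted standard deviation, amplitude from the profile range and offset
    from the minimum — robust starting points for unimodal marker curves.
    """
    z = profile.slice_positions_mm
    y = profile.mean_intensity
    if len(z) < 4:
        raise ValueError("need at least 4 samples to fit a Gaussian")
    rng_y = float(y.max() - y.min())
    if rng_y <= 0:
        raise ValueError("constant profile: no marker peak to fit")
    w = np.clip(y - y.min(), 0, None)
    mu0 = float(np.sum(w * z) / np.sum(w))
    sigma0 = float(np.sqrt(np.sum(w * (z - mu0) ** 2) / np.sum(w)))
    sigma0 = max(sigma0, (z[1] - z[0]) / 2.0)
    p0 = [rng_y, mu0, sigma0, float(y.min())]
    try:
        popt, _ = optimize.curve_fit(
            _gauss, z, y, p0=p0, maxfev=max_iterations,
            bounds=([0.0, z[0] - (z[-1] - z[0]), 1e-6, -np.inf],
                    [np.inf, z[-1] + (z[-1] - z[0]), np.inf, np.inf]))
    except RuntimeError as exc:
        best = GaussianFit(max(p0[0], 1e-12), p0[1], p0[2], p0[3],
                           float(np.sqrt(np.mean((_gauss(z, *p0) - y) ** 2))))
        raise FitFailureError(f"Gaussian fit did not converge: {exc}", best) from exc
    a, mu, sigma, b = popt
    rmse = float(np.sqrt(np.mean((_gauss(z, *popt) - y) ** 2)))
    return GaussianFit(float(a), float(mu), float(abs(sigma)), float(b), rmse)


def match_axial(pat_fit: GaussianFit, mri_marker_z_mm: float,
                pat_slice_positions_mm: np.ndarray) -> tuple[int, float]:
    """PAT slice matching the marked MRI slice, and the axial offset.

    Returns ``(index of PAT slice nearest the fitted peak,
    peak_mm - mri_marker_z_mm)``.  The offset converts nominal MRI z
    coordinates into the PAT frame.  Ties break toward the lower index.
    """
    pos = np.asarray(pat_slice_positions_mm, dtype=float)
    mu = pat_fit.mean_mm
    lo, hi = pos.min(), pos.max()
    dz = np.median(np.diff(pos)) if len(pos) > 1 else 0.0
    if mu < lo - dz / 2 or mu > hi + dz / 2:
        raise ValueError(f"fitted marker position {mu:.2f} mm outside PAT stack "
                         f"range [{lo:.2f}, {hi:.2f}] mm")
    d = np.abs(pos - mu)
    dmin = d.min()
    # ties (to floating tolerance) break toward the lower slice index
    idx = int(np.nonzero(d <= dmin + 1e-9)[0][0])
    return idx, float(mu - mri_marker_z_mm)


def consensus_offset(per_marker_offsets_mm: list[float]) -> float:
    """Median of per-marker offsets — robust to a single bad fit."""
    if len(per_marker_offsets_mm) == 0:
        raise ValueError("need at least one marker offset")
    return float(np.median(np.asarray(per_marker_offsets_mm, dtype=float)))


def align_stacks(pat: ImageVolume | MultispectralStack, mri: ImageVolume,
                 offset_mm: float) -> np.ndarray:
    """Nearest-slice pairing of MRI slices to PAT slices after offset correction.

    ``offset_mm`` maps nominal MRI positions into the PAT frame
    (``z_pat = z_mri + offset``).  Returns an integer array, one PAT slice
    index per MRI slice; the mapping is monotone non-decreasing by
    construction (nearest neighbour of a sorted sequence).
    """
    pat_vol = pat.volumes[0] if isinstance(pat, MultispectralStack) else pat
    pat_pos = pat_vol.origin[0] + np.arange(pat_vol.n_slices) * pat_vol.spacing[0]
    mri_pos = mri.slice_positions_mm() + offset_mm
    lo, hi = pat_pos.min(), pat_pos.max()
    if mri_pos.max() < lo or mri_pos.min() > hi:
        raise ValueError("no axial overlap between the stacks after offset correction")
    if mri_pos.min() < lo - pat_vol.spacing[0] or mri_pos.max() > hi + pat_vol.spacing[0]:
        warnings.warn("MRI stack extends beyond the PAT stack; edge slices "
                      "are paired with the boundary PAT slice")
    d = np.abs(mri_pos[:, None] - pat_pos[None, :])
    return np.argmin(d, axis=1).astype(int)


def register_axial(pat: ImageVolume | MultispectralStack, mri: ImageVolume,
                   markers: list[tuple[MarkerROI, float]],
                   z_window_mm: float = 6.0) -> tuple[float, np.ndarray, list[dict]]:
    """Convenience end-to-end axial registration.

    ``markers`` is a list of ``(PAT marker ROI, nominal MRI marker z in mm)``
    pairs.  For each marker the intensity profile is extracted in a window of
    ``±z_window_mm`` around the expected position, Gaussian-fitted, and an
    offset computed; the median offset then drives the full slice pairing.
    Returns ``(offset_mm, pairing, per-marker fit records)``.
    """
    pat_vol = pat.volumes[0] if isinstance(pat, MultispectralStack) else pat
    pat_pos = pat_vol.origin[0] + np.arange(pat_vol.n_slices) * pat_vol.spacing[0]
    offsets, records = [], []
    for i, (roi, mri_z) in enumerate(markers):
        lo = max(mri_z - z_window_mm, float(pat_pos.min()))
        hi = min(mri_z + z_window_mm, float(pat_pos.max()))
        profile = extract_marker_profile(pat, roi, (lo, hi))
        fit = fit_gaussian(profile)
        idx, off = match_axial(fit, mri_z, pat_pos)
        offsets.append(off)
        records.append({"marker": i, "mu_mm": fit.mean_mm, "sigma_mm": fit.sigma_mm,
                        "rmse": fit.rmse, "pat_slice": idx, "offset_mm": off})
    offset = consensus_offset(offsets)
    pairing = align_stacks(pat, mri, offset)
    return offset, pairing, records
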