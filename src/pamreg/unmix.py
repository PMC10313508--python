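"""Linear spectral unmixing of multispectral PAT into chromophore maps.

The reconstructed PAT value at wavelength lambda is modelled as the sum of
the absorption of the chromophores present in the voxel,

    p(lambda) = sum_i c_i * eps_i(lambda),

with ``c_i`` the concentration of chromophore ``i`` and ``eps_i(lambda)``
its molar extinction coefficient.  Given images at >= as many wavelengths
as chromophores this is a per-voxel linear system; the default solver is
non-negative least squares (concentrations are physical quantities), with
unconstrained least squares available for comparison.  From the recovered
oxy-/deoxy-hemoglobin maps the oxygen saturation map follows as

    SO2 = c_HbO2 / (c_HbO2 + c_Hb),

defined only where total hemoglobin exceeds a small threshold.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .volume import BinaryMask, ImageVolume, Modality, MultispectralStack


class IllPosedUnmixingError(ValueError):
    """Raised when the extinction matrix is (numerically) rank deficient."""


@dataclass
class ExtinctionTable:
    """Chromophore x wavelength extinction matrix.

    ``epsilon[i, j]`` is the extinction of chromophore ``i`` at wavelength
    ``j``.  Units only need to be mutually consistent; concentrations come
    out in the reciprocal unit.
    """

    chromophores: list[str]
    wavelengths_nm: list[float]
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = [float(w) for w in self.wavelengths_nm]
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape != (len(self.chromophores), len(self.wavelengths_nm)):
            raise ValueError("epsilon must be chromophore x wavelength")
        if (self.epsilon < 0).any():
            raise ValueError("extinction coefficients must be >= 0")

    def epsilon_of(self, chromophore: str, wavelength_nm: float) -> float:
        i = self.chromophores.index(chromophore)
        j = self.wavelengths_nm.index(float(wavelength_nm))
        return float(self.epsilon[i, j])

    def matrix_for(self, wavelengths_nm: list[float],
                   chromophores: list[str] | None = None) -> np.ndarray:
        """(n_wavelengths x n_chromophores) design matrix for the solve."""
        chroms = chromophores or self.chromophores
        rows = []
        for w in wavelengths_nm:
            if float(w) not in self.wavelengths_nm:
                raise KeyError(f"wavelength {w} nm not in extinction table")
            j = self.wavelengths_nm.index(float(w))
            rows.append([self.epsilon[self.chromophores.index(c), j] for c in chroms])
        return np.asarray(rows, dtype=float)

    @staticmethod
    def from_csv(path) -> "ExtinctionTable":
        """Read a CSV with header ``wavelength_nm`` then one column per chromophore."""
        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns:
            raise ValueError("extinction CSV must have a 'wavelength_nm' column")
        chroms = [c for c in df.columns if c != "wavelength_nm"]
        eps = df[chroms].to_numpy().T
        return ExtinctionTable(chroms, df["wavelength_nm"].tolist(), eps)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths_nm})
        for i, c in enumerate(self.chromophores):
            df[c] = self.epsilon[i]
        df.to_csv(path, index=False)


def default_table() -> ExtinctionTable:
    """Bundled Hb/HbO2/ICG extinction spectra at the five acquisition
    wavelengths, compiled from standard literature tabulations (values are
    reference data shipped as CSV, not outputs of this package)."""
    ref = importlib.resources.files("pamreg.data") / "extinction_hb_hbo2_icg.csv"
    with importlib.resources.as_file(ref) as path:
        return ExtinctionTable.from_csv(path)


def demo_table(chromophores: list[str] | None = None,
               wavelengths_nm: list[float] | None = None) -> ExtinctionTable:
    """A synthetic, well-conditioned table for phantoms and tests.

    Spectra are smooth, linearly independent shapes over the default
    wavelength range; algorithm validation should not hinge on literature
    spectral values, only on the linear model.
    """
    chroms = chromophores or ["HbO2", "Hb", "ICG"]
    lams = np.asarray(wavelengths_nm or [700.0, 730.0, 760.0, 800.0, 850.0])
    u = (lams - lams.min()) / (lams.max() - lams.min())  # 0..1
    shapes = {
        "HbO2": 0.3 + 0.7 * u,                        # rising
        "Hb": 1.0 - 0.7 * u,                          # falling
        "ICG": 0.2 + 0.9 * np.exp(-((u - 0.65) / 0.22) ** 2),  # peaked
    }
    eps = []
    for i, c in enumerate(chroms):
        if c in shapes:
            eps.append(shapes[c])
        else:  # extra chromophores: shifted bumps, still independent
            eps.append(0.2 + 0.8 * np.exp(-((u - 0.2 - 0.2 * i) / 0.18) ** 2))
    return ExtinctionTable(list(chroms), lams.tolist(), np.asarray(eps))


@dataclass
class ChromophoreMaps:
    """Per-chromophore concentration volumes plus the per-voxel residual norm."""

    maps: dict[str, ImageVolume]
    residual: ImageVolume
    mode: str = "nnls"

    def __getitem__(self, name: str) -> ImageVolume:
        return self.maps[name]

    def __contains__(self, name: str) -> bool:
        return name in self.maps

    @property
    def chromophores(self) -> list[str]:
        return list(self.maps)


@dataclass
class SO2Map:
    """Oxygen-saturation map in [0, 1] with an explicit validity mask."""

    values: ImageVolume
    valid: BinaryMask
    denom_threshold: float = 0.0


def _check_conditioning(E: np.ndarray, chromophores: list[str]) -> None:
    if E.shape[0] < E.shape[1]:
        raise IllPosedUnmixingError(
            f"{E.shape[0]} wavelengths cannot resolve {E.shape[1]} chromophores")
    if np.linalg.matrix_rank(E, tol=1e-10 * np.linalg.norm(E)) < E.shape[1]:
        # name the most collinear pair to aid diagnosis
        G = E / np.maximum(np.linalg.norm(E, axis=0, keepdims=True), 1e-300)
        C = np.abs(G.T @ G)
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        raise IllPosedUnmixingError(
            f"extinction matrix is rank deficient; chromophores "
            f"{chromophores[i]!r} and {chromophores[j]!r} are collinear")


def unmix(stack: MultispectralStack, table: ExtinctionTable,
          mode: str = "nnls") -> ChromophoreMaps:
    """Solve the per-voxel linear model for every voxel of the stack.

    ``mode='nnls'`` (default) constrains concentrations to be non-negative;
    ``mode='lsq'`` is the plain unconstrained solve.  The NNLS path first
    takes the cheap unconstrained solution and only re-solves, voxel by
    voxel, where that solution violates non-negativity — on physical data
    the vast majority of voxels never need the constrained solver.
    """
    if mode not in ("nnls", "lsq"):
        raise ValueError(f"unknown unmixing mode {mode!r}")
    E = table.matrix_for(stack.wavelengths_nm)
    chroms = list(table.chromophores)
    _check_conditioning(E, chroms)
    P = stack.as_array().reshape(len(stack), -1)  # (n_lam, n_vox)
    C, *_ = np.linalg.lstsq(E, P, rcond=None)
    if mode == "nnls":
        bad = np.where((C < 0).any(axis=0))[0]
        for v in bad:
            C[:, v], _ = optimize.nnls(E, P[:, v])
    R = E @ C - P
    resid = np.sqrt((R ** 2).sum(axis=0))
    shape = stack.shape
    spacing, origin = stack.spacing, stack.origin
    maps = {
        name: ImageVolume(C[i].reshape(shape), spacing, origin, Modality.MAP,
                          "concentration (a.u.)")
        for i, name in enumerate(chroms)
    }
    return ChromophoreMaps(maps, ImageVolume(resid.reshape(shape), spacing, origin,
                                             Modality.MAP, "residual"), mode)


def so2(maps: ChromophoreMaps, denom_threshold: float | None = None) -> SO2Map:
    """Oxygen saturation c_HbO2 / (c_HbO2 + c_Hb) on voxels with real signal.

    Voxels whose total hemoglobin falls at or below ``denom_threshold``
    (default ``1e-6 * max(HbT)``) are flagged invalid, never silently zero.
    """
    for required in ("HbO2", "Hb"):
        if required not in maps:
            raise KeyError(f"SO2 requires chromophore {required!r}")
    chbo2 = maps["HbO2"].data
    chb = maps["Hb"].data
    total = chbo2 + chb
    if denom_threshold is None:
        denom_threshold = 1e-6 * float(total.max()) if total.size else 0.0
    valid = total > denom_threshold
    values = np.zeros_like(total, dtype=np.float64)
    np.divide(chbo2, total, out=values, where=valid)
    values = np.clip(values, 0.0, 1.0)
    vol = maps["HbO2"]
    return SO2Map(ImageVolume(values, vol.spacing, vol.origin, Modality.MAP, "SO2"),
                  BinaryMask(valid, vol.spacing, vol.origin),
                  float(denom_threshold))


def hbt(maps: ChromophoreMaps) -> ImageVolume:
    """Total hemoglobin: voxelwise c_HbO2 + c_Hb."""
    for required in ("HbO2", "Hb"):
        if required not in maps:
            raise KeyError(f"HbT requires chromophore {required!r}")
    vol = maps["HbO2"]
    return ImageVolume(maps["HbO2"].data + maps["Hb"].data, vol.spacing, vol.origin,
                       Modality.MAP, "HbT (a.u.)")
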