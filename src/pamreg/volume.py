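"""Image volumes, masks and multispectral stacks with physical-spacing metadata.

Every stage of the pipeline exchanges :class:`ImageVolume` objects.  The
coordinate convention, stated once here and relied on everywhere else:

* arrays are indexed ``(z, y, x)`` with 0-based indices; ``z`` is the animal's
  long axis (the stacking / bed-translation direction);
* ``spacing = (dz, dy, dx)`` in millimetres, all strictly positive;
* voxels are *centred*: slice ``k`` sits at physical position
  ``origin_z + k * dz``, and likewise in-plane;
* all transforms and physical positions are expressed in millimetres.

NIfTI (``.nii`` / ``.nii.gz``) is the canonical on-disk format because it
carries spacing in its header.  Multi-page TIFF is supported for reading with
an explicit, caller-supplied spacing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import nibabel as nib
import numpy as np
import tifffile
from scipy import ndimage


class Modality(str, Enum):
    MRI = "MRI"
    PAT = "PAT"
    MASK = "MASK"
    MAP = "MAP"


class Plane(str, Enum):
    """Anatomical reslicing planes; XY is the native (axial) in-plane pair."""

    XY = "XY"
    XZ = "XZ"
    YZ = "YZ"


@dataclass
class ImageVolume:
    """A 3-D scalar volume with voxel spacing, origin and a modality tag.

    Parameters
    ----------
    data
        3-D array indexed ``(z, y, x)``.  Must contain no NaN.
    spacing
        ``(dz, dy, dx)`` voxel spacing in mm, each strictly positive.
    origin
        ``(z0, y0, x0)`` physical position of voxel ``(0, 0, 0)`` in mm.
    modality
        One of :class:`Modality`; informational but carried through I/O.
    intensity_units
        Free-text unit label (e.g. ``"a.u."``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.MAP
    intensity_units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and np.isnan(self.data).any():
            raise ValueError("volume data contains NaN")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def slice_positions_mm(self) -> np.ndarray:
        """Physical z position (mm) of each axial slice centre."""
        return self.origin[0] + np.arange(self.n_slices) * self.spacing[0]

    def get_slice(self, k: int) -> np.ndarray:
        return self.data[k]

    def copy_with(self, **kwargs) -> "ImageVolume":
        return replace(self, **kwargs)


@dataclass
class BinaryMask:
    """A 3-D boolean mask sharing the :class:`ImageVolume` geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be strictly in {0, 1}")
            arr = arr.astype(bool)
        if arr.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def to_volume(self) -> ImageVolume:
        return ImageVolume(
            self.data.astype(np.uint8), self.spacing, self.origin, Modality.MASK, "binary"
        )


@dataclass
class MultispectralStack:
    """Ordered set of co-located PAT volumes, one per illumination wavelength."""

    volumes: list[ImageVolume]
    wavelengths_nm: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths_nm = [float(w) for w in self.wavelengths_nm]
        if len(self.volumes) != len(self.wavelengths_nm):
            raise ValueError("one volume per wavelength required")
        if len(self.wavelengths_nm) == 0:
            raise ValueError("stack must contain at least one wavelength")
        if any(b <= a for a, b in zip(self.wavelengths_nm, self.wavelengths_nm[1:])):
            raise ValueError("wavelengths must be strictly increasing")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if v.shape != ref.shape or v.spacing != ref.spacing or v.origin != ref.origin:
                raise ValueError("all member volumes must share shape, spacing and origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volumes[0].spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.volumes[0].origin

    def __len__(self) -> int:
        return len(self.volumes)

    def as_array(self) -> np.ndarray:
        """Stack to a 4-D array indexed ``(wavelength, z, y, x)``."""
        return np.stack([v.data for v in self.volumes], axis=0)


# ---------------------------------------------------------------------------
# I/O


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def _is_tiff(path: str) -> bool:
    return path.endswith((".tif", ".tiff"))


def read_volume(
    path: str,
    spacing_override: Sequence[float] | None = None,
    modality: Modality | str = Modality.MAP,
) -> ImageVolume:
    """Read a NIfTI or multi-page TIFF volume, normalising axis order to (z, y, x).

    NIfTI files are written/read with the array stored ``(x, y, z)`` on disk
    (the format's convention); the header zooms supply the spacing.  TIFF
    carries no reliable spacing, so ``spacing_override`` is mandatory there.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if _is_nifti(path):
        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise IOError(f"expected a 3-D NIfTI volume, got ndim={arr.ndim}: {path}")
        data = np.ascontiguousarray(arr.T)  # (x, y, z) -> (z, y, x)
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        origin = (0.0, 0.0, 0.0)
        if img.affine is not None:
            t = img.affine[:3, 3]
            origin = (float(t[2]), float(t[1]), float(t[0]))
        if spacing_override is not None:
            spacing = tuple(float(s) for s in spacing_override)  # type: ignore[assignment]
    elif _is_tiff(path):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if spacing_override is None:
            raise ValueError(
                f"TIFF carries no spacing metadata; pass spacing_override for {path}"
            )
        spacing = tuple(float(s) for s in spacing_override)  # type: ignore[assignment]
        origin = (0.0, 0.0, 0.0)
    else:
        raise IOError(f"unsupported volume format: {path}")
    if np.issubdtype(data.dtype, np.floating) and np.isnan(data).any():
        raise ValueError(f"volume contains NaN on load: {path}")
    return ImageVolume(data, spacing, origin, Modality(modality))


def write_volume(vol: ImageVolume | BinaryMask, path: str) -> None:
    """Write a volume (or mask) as NIfTI-1, preserving spacing and origin."""
    if isinstance(vol, BinaryMask):
        vol = vol.to_volume()
    if not _is_nifti(path):
        raise IOError(f"write_volume emits NIfTI only (.nii/.nii.gz), got {path}")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    dz, dy, dx = vol.spacing
    z0, y0, x0 = vol.origin
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = (x0, y0, z0)
    img = nib.Nifti1Image(np.ascontiguousarray(vol.data.T), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, path)


def read_stack(paths: Sequence[str], wavelengths_nm: Sequence[float], **kwargs) -> MultispectralStack:
    """Read one volume per wavelength into a :class:`MultispectralStack`."""
    vols = [read_volume(p, modality=Modality.PAT, **kwargs) for p in paths]
    return MultispectralStack(vols, list(wavelengths_nm))


# ---------------------------------------------------------------------------
# Reslicing


def reslice(vol: ImageVolume, plane: Plane | str) -> ImageVolume:
    """Resample so the requested plane becomes the in-plane axis pair.

    The axial (XY) stack is typically anisotropic (slice spacing ≫ pixel
    size); sagittal and coronal views are produced by transposing axes and
    linearly interpolating the formerly axial direction down to the finer
    in-plane pixel size, giving isotropic in-plane sampling at
    ``min(dy, dx)``.
    """
    plane = Plane(plane)
    if plane is Plane.XY:
        return vol.copy_with(data=vol.data.copy())
    dz, dy, dx = vol.spacing
    if vol.n_slices < 2:
        raise ValueError("reslicing out of plane requires >= 2 axial slices")
    target = min(dy, dx)
    zoom_z = dz / target
    data = ndimage.zoom(vol.data.astype(np.float64), (zoom_z, 1.0, 1.0), order=1)
    if plane is Plane.XZ:
        # in-plane axes (z, x); stacked along y
        out = np.transpose(data, (1, 0, 2))
        spacing = (dy, target, dx)
        origin = (vol.origin[1], vol.origin[0], vol.origin[2])
    else:  # YZ: in-plane axes (z, y); stacked along x
        out = np.transpose(data, (2, 0, 1))
        spacing = (dx, target, dy)
        origin = (vol.origin[2], vol.origin[0], vol.origin[1])
    return ImageVolume(out, spacing, origin, vol.modality, vol.intensity_units)


# ---------------------------------------------------------------------------
# Transform (de)serialisation lives with I/O so every module shares one format.

TRANSFORM_JSON_FIELDS = ("type", "theta_deg", "tx_mm", "ty_mm", "scale", "center_mm")
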