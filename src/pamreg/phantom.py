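"""Digital mouse-like phantom with paired MRI / multispectral PAT renderings.

The phantom emulates the study conditions of successive photoacoustic (PAT)
and MR imaging of a small animal on a shared bed:

* a soft-tissue **body** (elliptical cylinder along the animal's long axis z),
* internal **organs** and a **tumor** with a hypoxic core and perfused rim,
* superficial **vessels** (strong optical absorbers, PAT-dominant),
* sub-millimetre ink **fiducial markers** on the skin surface spaced 10 mm
  apart along z — rendered *hypointense* in MRI and as strong, spectrally
  flat absorbers in PAT, axially smeared so a marker that occupies one MRI
  slice is visible across ~5 mm of PAT slices,
* ground-truth **chromophore concentration fields** (HbO2, Hb, ICG) from
  which the multispectral PAT signal is generated through the linear
  absorption model ``p(lambda) = sum_i c_i * eps_i(lambda)``,
* a known per-slice rigid **misalignment** emulating animal motion during
  the modality switch, plus an axial offset between the two stacks.

Geometry is expressed in mm with the in-plane origin at the body centre and
z = 0 at the first slice.  MRI defaults mirror a 250x250 matrix over a
25x25 mm field of view at 1.0 mm slice spacing; PAT defaults mirror 300x300
over 30x30 mm with configurable axial step (0.3 mm default).  All randomness
flows through ``numpy.random.default_rng`` (PCG64) seeded from the scene, so
renders are bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .transforms import RigidTransform2D, apply_transform
from .unmix import ExtinctionTable
from .volume import BinaryMask, ImageVolume, Modality, MultispectralStack

MRI_GRID = (250, 250)
MRI_SPACING_INPLANE = (0.1, 0.1)
MRI_SLICE_SPACING = 1.0
PAT_GRID = (300, 300)
PAT_SPACING_INPLANE = (0.1, 0.1)
PAT_SLICE_SPACING = 0.3
DEFAULT_WAVELENGTHS = [700.0, 730.0, 760.0, 800.0, 850.0]
MARKER_AXIAL_SIGMA_MM = 1.3  # ~5 mm visible spread at default thresholds


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid region with per-modality appearance."""

    center: tuple[float, float, float]  # (z, y, x) mm
    semi_axes: tuple[float, float, float]  # (az, ay, ax) mm
    mri_intensity: float = 120.0
    chromophores: dict[str, float] = field(default_factory=dict)  # name -> conc (a.u.)

    def contains(self, zz, yy, xx) -> np.ndarray:
        cz, cy, cx = self.center
        az, ay, ax = self.semi_axes
        return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


@dataclass
class Vessel:
    """Thin bright tube running along z at a fixed in-plane position."""

    center_yx: tuple[float, float]
    radius_mm: float = 0.3
    z_range: tuple[float, float] = (0.0, 1e9)
    chromophores: dict[str, float] = field(default_factory=lambda: {"HbO2": 30.0, "Hb": 10.0})
    mri_intensity: float | None = None  # None: invisible in MRI


@dataclass
class Marker:
    """Surface ink fiducial: dark dot in MRI, strong flat absorber in PAT."""

    z_mm: float
    angle_deg: float = 90.0  # position around the body perimeter
    diameter_mm: float = 0.8


@dataclass
class PhantomScene:
    """Complete scene description; every field has a study-condition default."""

    body_semi_axes_yx: tuple[float, float] = (8.0, 10.0)  # (ay, ax) mm
    z_extent_mm: float = 30.0
    skin_thickness_mm: float = 0.5
    organs: list[Ellipsoid] = field(default_factory=list)
    tumor: Ellipsoid | None = None
    tumor_core_fraction: float = 0.5  # core semi-axes as fraction of tumor's
    vessels: list[Vessel] = field(default_factory=list)
    markers: list[Marker] = field(default_factory=list)
    body_mri_intensity: float = 100.0
    body_chromophores: dict[str, float] = field(
        default_factory=lambda: {"HbO2": 5.0, "Hb": 5.0, "ICG": 0.0}
    )
    skin_chromophores: dict[str, float] = field(
        default_factory=lambda: {"HbO2": 6.0, "Hb": 10.0, "ICG": 0.0}
    )
    tumor_core_mri_intensity: float = 60.0
    tumor_core_chromophores: dict[str, float] = field(
        default_factory=lambda: {"HbO2": 3.0, "Hb": 12.0, "ICG": 0.5}
    )
    marker_pat_amplitude: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_extent_mm <= 0:
            raise ValueError("z extent must be positive")
        for m in self.markers:
            if m.diameter_mm >= 1.0:
                raise ValueError("marker diameter must be < 1 mm")
        ay, ax = self.body_semi_axes_yx
        for organ in list(self.organs) + ([self.tumor] if self.tumor else []):
            _, oy, ox = organ.center
            _, sy, sx = organ.semi_axes
            if (abs(oy) + sy) > ay or (abs(ox) + sx) > ax:
                raise ValueError("all organs must be contained inside the body")
        for name, c in self.body_chromophores.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")

    @property
    def chromophore_names(self) -> list[str]:
        names = list(self.body_chromophores)
        return names

    # -- geometry helpers ---------------------------------------------------

    def grid_coords(self, grid_yx: tuple[int, int], spacing: tuple[float, float, float],
                    n_slices: int):
        """Voxel-centre coordinate arrays (zz, yy, xx) on a centred grid."""
        dz, dy, dx = spacing
        ny, nx = grid_yx
        z = np.arange(n_slices) * dz
        y = (np.arange(ny) - (ny - 1) / 2.0) * dy
        x = (np.arange(nx) - (nx - 1) / 2.0) * dx
        return np.meshgrid(z, y, x, indexing="ij")

    def origin_for(self, grid_yx: tuple[int, int], spacing: tuple[float, float, float]
                   ) -> tuple[float, float, float]:
        dz, dy, dx = spacing
        ny, nx = grid_yx
        return (0.0, -(ny - 1) / 2.0 * dy, -(nx - 1) / 2.0 * dx)

    def body_mask_on(self, zz, yy, xx) -> np.ndarray:
        ay, ax = self.body_semi_axes_yx
        inplane = (yy / ay) ** 2 + (xx / ax) ** 2 <= 1.0
        return inplane & (zz >= 0) & (zz <= self.z_extent_mm)

    def marker_position_yx(self, marker: Marker) -> tuple[float, float]:
        """In-plane centre of a surface marker, just inside the skin."""
        ay, ax = self.body_semi_axes_yx
        phi = math.radians(marker.angle_deg)
        r = 1.0 - (marker.diameter_mm / 2.0 + 0.05) / min(ay, ax)
        return (r * ay * math.sin(phi), r * ax * math.cos(phi))


def default_scene(seed: int = 0, z_extent_mm: float = 30.0,
                  marker_spacing_mm: float = 10.0, n_markers: int | None = None,
                  with_markers: bool = True) -> PhantomScene:
    """The standard phantom: two organs, a rim/core tumor, three vessels,
    and surface markers every 10 mm starting 5 mm into the stack."""
    zc = z_extent_mm / 2.0
    organs = [
        Ellipsoid((zc - 0.15 * z_extent_mm, -2.5, -4.5), (0.25 * z_extent_mm, 2.6, 3.0),
                  mri_intensity=150.0,
                  chromophores={"HbO2": 9.0, "Hb": 6.0, "ICG": 0.0}),
        Ellipsoid((zc + 0.12 * z_extent_mm, 2.8, 4.0), (0.2 * z_extent_mm, 2.2, 2.6),
                  mri_intensity=135.0,
                  chromophores={"HbO2": 6.0, "Hb": 9.0, "ICG": 0.0}),
    ]
    tumor = Ellipsoid((zc, -3.0, 5.5), (0.22 * z_extent_mm, 2.4, 2.6),
                      mri_intensity=175.0,
                      chromophores={"HbO2": 14.0, "Hb": 5.0, "ICG": 8.0})
    vessels = [
        Vessel((-6.2, 0.0), 0.35),
        Vessel((5.8, -3.0), 0.3),
        Vessel((4.5, 6.5), 0.25),
    ]
    markers = []
    if with_markers:
        z = 5.0
        k = 0
        while z < z_extent_mm - 1.0 and (n_markers is None or k < n_markers):
            markers.append(Marker(z_mm=z, angle_deg=90.0, diameter_mm=0.8))
            z += marker_spacing_mm
            k += 1
    return PhantomScene(organs=organs, tumor=tumor, vessels=vessels,
                        markers=markers, z_extent_mm=z_extent_mm, seed=seed)


# ---------------------------------------------------------------------------
# Rasterisation


def _paint_regions(scene: PhantomScene, zz, yy, xx, *, mri: bool):
    """Rasterise the scene; returns (mri_image,) or chromophore field dict."""
    body = scene.body_mask_on(zz, yy, xx)
    ay, ax = scene.body_semi_axes_yx
    rr = (yy / ay) ** 2 + (xx / ax) ** 2
    t = scene.skin_thickness_mm / min(ay, ax)
    skin = body & (rr >= (1.0 - t) ** 2)

    names = scene.chromophore_names
    if mri:
        out = np.zeros(zz.shape, dtype=np.float64)
        out[body] = scene.body_mri_intensity
    else:
        fields = {n: np.zeros(zz.shape, dtype=np.float64) for n in names}
        for n in names:
            fields[n][body] = scene.body_chromophores.get(n, 0.0)
        for n in names:
            fields[n][skin] = scene.skin_chromophores.get(n, 0.0)

    for organ in scene.organs:
        m = organ.contains(zz, yy, xx)
        if mri:
            out[m] = organ.mri_intensity
        else:
            for n in names:
                fields[n][m] = organ.chromophores.get(n, 0.0)

    if scene.tumor is not None:
        tm = scene.tumor.contains(zz, yy, xx)
        core = Ellipsoid(scene.tumor.center,
                         tuple(s * scene.tumor_core_fraction for s in scene.tumor.semi_axes))
        cm = core.contains(zz, yy, xx)
        if mri:
            out[tm] = scene.tumor.mri_intensity
            out[cm] = scene.tumor_core_mri_intensity
        else:
            for n in names:
                fields[n][tm] = scene.tumor.chromophores.get(n, 0.0)
                fields[n][cm] = scene.tumor_core_chromophores.get(n, 0.0)

    for vessel in scene.vessels:
        vy, vx = vessel.center_yx
        vm = ((yy - vy) ** 2 + (xx - vx) ** 2 <= vessel.radius_mm ** 2) & body
        vm &= (zz >= vessel.z_range[0]) & (zz <= vessel.z_range[1])
        if mri:
            if vessel.mri_intensity is not None:
                out[vm] = vessel.mri_intensity
        else:
            for n in names:
                fields[n][vm] = np.maximum(fields[n][vm], vessel.chromophores.get(n, 0.0))

    return out if mri else fields


def chromophore_fields(scene: PhantomScene, grid: tuple[int, int] = PAT_GRID,
                       spacing: tuple[float, float, float] = (PAT_SLICE_SPACING, 0.1, 0.1),
                       n_slices: int | None = None) -> dict[str, np.ndarray]:
    """Ground-truth concentration fields (a.u.) rasterised on a PAT grid."""
    if n_slices is None:
        n_slices = int(round(scene.z_extent_mm / spacing[0])) + 1
    zz, yy, xx = scene.grid_coords(grid, spacing, n_slices)
    return _paint_regions(scene, zz, yy, xx, mri=False)


def _marker_field(scene: PhantomScene, zz, yy, xx, axial_sigma_mm: float,
                  dz: float) -> np.ndarray:
    """Spectrally flat ink-absorber field, Gaussian-smeared along z."""
    out = np.zeros(zz.shape, dtype=np.float64)
    for marker in scene.markers:
        my, mx = scene.marker_position_yx(marker)
        r = marker.diameter_mm / 2.0
        inplane = (yy[0] - my) ** 2 + (xx[0] - mx) ** 2 <= r ** 2
        zprof = np.zeros(zz.shape[0])
        zpos = zz[:, 0, 0]
        if axial_sigma_mm > 0:
            zprof = np.exp(-0.5 * ((zpos - marker.z_mm) / axial_sigma_mm) ** 2)
        else:
            k = int(np.argmin(np.abs(zpos - marker.z_mm)))
            zprof[k] = 1.0
        out += scene.marker_pat_amplitude * zprof[:, None, None] * inplane[None, :, :]
    return out


def render_mri(scene: PhantomScene, grid: tuple[int, int] = MRI_GRID,
               spacing: tuple[float, float, float] = (MRI_SLICE_SPACING, 0.1, 0.1),
               n_slices: int | None = None, noise_sigma: float = 2.0) -> ImageVolume:
    """T2-like MRI rendering: organ intensities, hypointense surface markers,
    additive Gaussian noise. Deterministic given ``scene.seed``."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if n_slices is None:
        n_slices = int(round(scene.z_extent_mm / spacing[0]))
    ny, nx = grid
    ay, ax = scene.body_semi_axes_yx
    if ay * 2 > ny * spacing[1] or ax * 2 > nx * spacing[2]:
        raise ValueError("grid too small to contain the phantom body")
    zz, yy, xx = scene.grid_coords(grid, spacing, n_slices)
    img = _paint_regions(scene, zz, yy, xx, mri=True)
    # markers: dark dots on the slice whose centre is nearest each marker
    zpos = zz[:, 0, 0]
    for marker in scene.markers:
        k = int(np.argmin(np.abs(zpos - marker.z_mm)))
        my, mx = scene.marker_position_yx(marker)
        r = marker.diameter_mm / 2.0
        dot = (yy[k] - my) ** 2 + (xx[k] - mx) ** 2 <= r ** 2
        img[k][dot] = 0.0
    if noise_sigma > 0:
        rng = np.random.default_rng(scene.seed * 1000003 + 11)
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return ImageVolume(img, spacing, scene.origin_for(grid, spacing), Modality.MRI)


def render_pat(scene: PhantomScene, extinction: ExtinctionTable,
               wavelengths_nm: list[float] | None = None,
               grid: tuple[int, int] = PAT_GRID,
               spacing: tuple[float, float, float] = (PAT_SLICE_SPACING, 0.1, 0.1),
               n_slices: int | None = None,
               marker_axial_sigma_mm: float = MARKER_AXIAL_SIGMA_MM,
               noise_sigma: float = 0.0,
               include_markers: bool = True) -> MultispectralStack:
    """Multispectral PAT rendering through the linear absorption model.

    Per wavelength the voxel value is ``sum_i c_i * eps_i(lambda)`` plus,
    when ``include_markers``, a spectrally flat ink term smeared along z by a
    Gaussian of std ``marker_axial_sigma_mm`` (default tuned so a marker's
    visible spread covers roughly 5 mm of slices), plus additive Gaussian
    noise.  Deterministic given ``scene.seed``.
    """
    if wavelengths_nm is None:
        wavelengths_nm = list(DEFAULT_WAVELENGTHS)
    for w in wavelengths_nm:
        if w not in extinction.wavelengths_nm:
            raise KeyError(f"wavelength {w} nm missing from extinction table")
    for name in scene.chromophore_names:
        if name not in extinction.chromophores:
            raise KeyError(f"chromophore {name!r} missing from extinction table")
    if n_slices is None:
        n_slices = int(round(scene.z_extent_mm / spacing[0])) + 1
    zz, yy, xx = scene.grid_coords(grid, spacing, n_slices)
    fields = _paint_regions(scene, zz, yy, xx, mri=False)
    ink = None
    if include_markers and scene.markers:
        ink = _marker_field(scene, zz, yy, xx, marker_axial_sigma_mm, spacing[0])
    rng = np.random.default_rng(scene.seed * 1000003 + 29)
    origin = scene.origin_for(grid, spacing)
    vols = []
    for lam in wavelengths_nm:
        p = np.zeros(zz.shape, dtype=np.float64)
        for name, c in fields.items():
            p += c * extinction.epsilon_of(name, lam)
        if ink is not None:
            p += ink  # ink: flat absorption spectrum
        if noise_sigma > 0:
            p = p + rng.normal(0.0, noise_sigma, p.shape)
        vols.append(ImageVolume(p, spacing, origin, Modality.PAT))
    return MultispectralStack(vols, [float(w) for w in wavelengths_nm])


def ground_truth_masks(scene: PhantomScene, grid: tuple[int, int],
                       spacing: tuple[float, float, float],
                       n_slices: int) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Analytic rasterisation of (body, tumor, tumor core) masks."""
    zz, yy, xx = scene.grid_coords(grid, spacing, n_slices)
    origin = scene.origin_for(grid, spacing)
    body = scene.body_mask_on(zz, yy, xx)
    if scene.tumor is not None:
        tumor = scene.tumor.contains(zz, yy, xx)
        core_ell = Ellipsoid(scene.tumor.center,
                             tuple(s * scene.tumor_core_fraction for s in scene.tumor.semi_axes))
        core = core_ell.contains(zz, yy, xx)
    else:
        tumor = np.zeros_like(body)
        core = np.zeros_like(body)
    return (BinaryMask(body, spacing, origin),
            BinaryMask(tumor & body, spacing, origin),
            BinaryMask(core & tumor & body, spacing, origin))


# ---------------------------------------------------------------------------
# Misalignment model


@dataclass
class MisalignmentModel:
    """Known ground-truth perturbation applied to the MRI stack.

    One in-plane rigid transform per MRI slice (global motion plus small
    independent per-slice jitter) and a global axial offset between the two
    stacks' coordinate systems.
    """

    per_slice_transforms: list[RigidTransform2D]
    axial_offset_mm: float = 0.0
    max_translation_mm: float = 3.0
    max_rotation_deg: float = 10.0

    def __post_init__(self) -> None:
        for t in self.per_slice_transforms:
            if (abs(t.tx) > self.max_translation_mm + 1e-9
                    or abs(t.ty) > self.max_translation_mm + 1e-9
                    or abs(t.theta_deg) > self.max_rotation_deg + 1e-9):
                raise ValueError("per-slice transform exceeds stated magnitude bounds")


def random_misalignment(n_slices: int, seed: int = 0, *,
                        global_translation_mm: float = 2.0,
                        global_rotation_deg: float = 5.0,
                        jitter_translation_mm: float = 0.4,
                        jitter_rotation_deg: float = 1.0,
                        axial_offset_mm: float = 0.0,
                        max_translation_mm: float = 3.0,
                        max_rotation_deg: float = 10.0) -> MisalignmentModel:
    """Draw a global rigid motion plus independent per-slice jitter.

    The split mirrors what happens physically: the animal shifts once during
    the modality switch (global term) and breathes/settles slightly slice to
    slice (jitter term).  Per-slice 2-D registration can undo both, a single
    3-D rigid fit only the global part.
    """
    rng = np.random.default_rng(seed)
    g_tx, g_ty = rng.uniform(-global_translation_mm, global_translation_mm, 2)
    g_th = math.radians(rng.uniform(-global_rotation_deg, global_rotation_deg))
    transforms = []
    for _ in range(n_slices):
        jx, jy = rng.normal(0.0, jitter_translation_mm, 2)
        jt = math.radians(rng.normal(0.0, jitter_rotation_deg))
        tx = float(np.clip(g_tx + jx, -max_translation_mm, max_translation_mm))
        ty = float(np.clip(g_ty + jy, -max_translation_mm, max_translation_mm))
        th = float(np.clip(g_th + jt, -math.radians(max_rotation_deg),
                           math.radians(max_rotation_deg)))
        transforms.append(RigidTransform2D(th, tx, ty, center=(0.0, 0.0)))
    return MisalignmentModel(transforms, axial_offset_mm,
                             max_translation_mm, max_rotation_deg)


def apply_misalignment(mri: ImageVolume, model: MisalignmentModel,
                       fill: float = 0.0) -> ImageVolume:
    """Warp each MRI slice by its transform and shift the stack axially.

    The grid is unchanged; the axial offset is realised by shifting the
    volume's z origin, so the perturbed stack *believes* its slices sit at
    different physical z than they truly do — exactly what fiducial-based
    axial registration must recover.
    """
    if len(model.per_slice_transforms) != mri.n_slices:
        raise ValueError(
            f"need one transform per slice: {len(model.per_slice_transforms)} "
            f"vs {mri.n_slices} slices")
    dz, dy, dx = mri.spacing
    y0 = mri.origin[1]
    x0 = mri.origin[2]
    out = np.empty_like(mri.data, dtype=np.float64)
    for k, t in enumerate(model.per_slice_transforms):
        out[k] = apply_transform(mri.data[k], t, spacing=(dy, dx),
                                 origin=(y0, x0), fill=fill)
    origin = (mri.origin[0] - model.axial_offset_mm, y0, x0)
    return ImageVolume(out, mri.spacing, origin, mri.modality, mri.intensity_units)
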