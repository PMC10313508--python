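"""Rigid and similarity transforms in physical (mm) coordinates.

A 2-D transform maps an in-plane physical point ``p = (x, y)`` (mm) as

    p' = s * R(theta) @ (p - c) + c + t

with rotation ``R`` by ``theta`` (radians, counter-clockwise), translation
``t = (tx, ty)`` in mm, and rotation centre ``c`` (defaults to the image
centre).  A rigid transform is the ``s = 1`` special case.  Images are
resampled by inverse mapping with bilinear interpolation, so transform
parameters always describe the *forward* motion of image content.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def _wrap_angle(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    t = (float(theta) + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if t == -math.pi else t


@dataclass
class RigidTransform2D:
    """In-plane rotation + translation about a stated centre (all mm / rad)."""

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)  # (cx, cy) mm

    def __post_init__(self) -> None:
        self.theta = _wrap_angle(self.theta)
        self.center = (float(self.center[0]), float(self.center[1]))

    @property
    def scale(self) -> float:
        return 1.0

    @property
    def theta_deg(self) -> float:
        return math.degrees(self.theta)

    def rotation_matrix(self) -> np.ndarray:
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply_points(self, pts_xy: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) mm points forward."""
        pts = np.atleast_2d(np.asarray(pts_xy, dtype=float))
        c = np.asarray(self.center)
        t = np.array([self.tx, self.ty])
        return (self.scale * (self.rotation_matrix() @ (pts - c).T)).T + c + t

    def inverse(self) -> "RigidTransform2D":
        R = self.rotation_matrix()
        t_inv = -(R.T @ np.array([self.tx, self.ty])) / self.scale
        return type(self)(**self._inverse_kwargs(t_inv))

    def _inverse_kwargs(self, t_inv: np.ndarray) -> dict:
        return dict(theta=-self.theta, tx=float(t_inv[0]), ty=float(t_inv[1]),
                    center=self.center)

    def compose(self, first: "RigidTransform2D") -> "SimilarityTransform2D | RigidTransform2D":
        """Return the transform equivalent to applying ``first`` then ``self``.

        Both transforms must share the same centre.
        """
        if not np.allclose(self.center, first.center):
            raise ValueError("compose requires a common rotation centre")
        R2 = self.rotation_matrix()
        t1 = np.array([first.tx, first.ty])
        t = self.scale * (R2 @ t1) + np.array([self.tx, self.ty])
        theta = self.theta + first.theta
        s = self.scale * first.scale
        if math.isclose(s, 1.0, abs_tol=1e-15):
            return RigidTransform2D(theta, float(t[0]), float(t[1]), self.center)
        return SimilarityTransform2D(theta, float(t[0]), float(t[1]), self.center, s)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "type": "rigid" if self.scale == 1.0 else "similarity",
            "theta_deg": self.theta_deg,
            "tx_mm": self.tx,
            "ty_mm": self.ty,
            "scale": self.scale,
            "center_mm": list(self.center),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform2D":
        kind = d.get("type", "rigid")
        theta = math.radians(float(d["theta_deg"]))
        center = tuple(d.get("center_mm", (0.0, 0.0)))
        if kind == "similarity" or float(d.get("scale", 1.0)) != 1.0:
            return SimilarityTransform2D(theta, float(d["tx_mm"]), float(d["ty_mm"]),
                                         center, float(d.get("scale", 1.0)))
        return RigidTransform2D(theta, float(d["tx_mm"]), float(d["ty_mm"]), center)

    @staticmethod
    def from_json(path: str) -> "RigidTransform2D":
        with open(path) as fh:
            return RigidTransform2D.from_dict(json.load(fh))


@dataclass
class SimilarityTransform2D(RigidTransform2D):
    """Rigid transform plus an isotropic scale ``s > 0`` (non-reflective)."""

    s: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.s <= 0:
            raise ValueError("similarity scale must be > 0")

    @property
    def scale(self) -> float:
        return self.s

    def _inverse_kwargs(self, t_inv: np.ndarray) -> dict:
        kw = super()._inverse_kwargs(t_inv)
        kw["s"] = 1.0 / self.s
        return kw


def image_center_mm(shape: tuple[int, int], spacing: tuple[float, float],
                    origin: tuple[float, float] = (0.0, 0.0)) -> tuple[float, float]:
    """Physical (x, y) centre of a 2-D grid with spacing (dy, dx)."""
    h, w = shape
    dy, dx = spacing
    y0, x0 = origin
    return (x0 + (w - 1) * dx / 2.0, y0 + (h - 1) * dy / 2.0)


def apply_transform(
    img: np.ndarray,
    transform: RigidTransform2D,
    spacing: tuple[float, float] = (1.0, 1.0),
    origin: tuple[float, float] = (0.0, 0.0),
    fill: float = 0.0,
    order: int = 1,
) -> np.ndarray:
    """Warp a 2-D image by a forward transform (inverse-mapped, bilinear).

    ``spacing`` is ``(dy, dx)`` mm and ``origin`` is ``(y0, x0)`` mm; the
    output grid equals the input grid, with out-of-bounds samples set to
    ``fill``.
    """
    img = np.asarray(img)
    h, w = img.shape
    dy, dx = spacing
    y0, x0 = origin
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    xs = x0 + jj * dx
    ys = y0 + ii * dy
    inv = transform.inverse()
    R = inv.rotation_matrix() * inv.scale
    cx, cy = inv.center
    # inverse-map output physical coords back into the input image
    xr = xs - cx
    yr = ys - cy
    xin = R[0, 0] * xr + R[0, 1] * yr + cx + inv.tx
    yin = R[1, 0] * xr + R[1, 1] * yr + cy + inv.ty
    rows = (yin - y0) / dy
    cols = (xin - x0) / dx
    return ndimage.map_coordinates(
        img.astype(np.float64), [rows, cols], order=order, cval=float(fill), mode="constant"
    )


# ---------------------------------------------------------------------------
# 3-D rigid / similarity (whole-volume registration variant)


@dataclass
class RigidTransform3D:
    """Volume transform: rotations (deg→rad internally) about x/y/z + translation.

    ``p' = s * Rz(rz) Ry(ry) Rx(rx) @ (p - c) + c + t`` with ``p = (x, y, z)``
    in mm.  ``scale`` fixed at 1 for the rigid case.
    """

    rx: float = 0.0  # radians
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0  # mm
    ty: float = 0.0
    tz: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (cx, cy, cz)
    s: float = 1.0

    @property
    def scale(self) -> float:
        return self.s

    def rotation_matrix(self) -> np.ndarray:
        cx_, sx = math.cos(self.rx), math.sin(self.rx)
        cy_, sy = math.cos(self.ry), math.sin(self.ry)
        cz_, sz = math.cos(self.rz), math.sin(self.rz)
        Rx = np.array([[1, 0, 0], [0, cx_, -sx], [0, sx, cx_]])
        Ry = np.array([[cy_, 0, sy], [0, 1, 0], [-sy, 0, cy_]])
        Rz = np.array([[cz_, -sz, 0], [sz, cz_, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def to_dict(self) -> dict:
        return {
            "type": "rigid3d" if self.s == 1.0 else "similarity3d",
            "rx_deg": math.degrees(self.rx),
            "ry_deg": math.degrees(self.ry),
            "rz_deg": math.degrees(self.rz),
            "tx_mm": self.tx,
            "ty_mm": self.ty,
            "tz_mm": self.tz,
            "scale": self.s,
            "center_mm": list(self.center),
        }


def apply_transform_3d(
    data: np.ndarray,
    transform: RigidTransform3D,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    fill: float = 0.0,
    order: int = 1,
) -> np.ndarray:
    """Warp a (z, y, x) volume by a forward 3-D transform (inverse mapping)."""
    dz, dy, dx = spacing
    z0, y0, x0 = origin
    R = transform.rotation_matrix() * transform.scale
    Rinv = np.linalg.inv(R)
    c = np.asarray(transform.center, dtype=float)  # (cx, cy, cz)
    t = np.array([transform.tx, transform.ty, transform.tz])
    # affine on index coordinates: idx_in = A @ idx_out + b, working in (z,y,x)
    S_out = np.diag([dx, dy, dz])  # maps (j, i, k) -> (x, y, z) offsets
    # build mapping in (x,y,z) then convert axes order for map_coordinates
    # p_in = Rinv @ (p_out - c - t) + c
    nz, ny, nx = data.shape
    kk, ii, jj = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    xs = x0 + jj * dx
    ys = y0 + ii * dy
    zs = z0 + kk * dz
    px = xs - c[0] - t[0]
    py = ys - c[1] - t[1]
    pz = zs - c[2] - t[2]
    xin = Rinv[0, 0] * px + Rinv[0, 1] * py + Rinv[0, 2] * pz + c[0]
    yin = Rinv[1, 0] * px + Rinv[1, 1] * py + Rinv[1, 2] * pz + c[1]
    zin = Rinv[2, 0] * px + Rinv[2, 1] * py + Rinv[2, 2] * pz + c[2]
    del S_out
    coords = [(zin - z0) / dz, (yin - y0) / dy, (xin - x0) / dx]
    return ndimage.map_coordinates(
        data.astype(np.float64), coords, order=order, cval=float(fill), mode="constant"
    )
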