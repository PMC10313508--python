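"""Fused outputs and the run report bundle.

Overlay convention: PAT in magenta (red+blue), registered MRI in green, each
min–max normalised per slice, so structures present in both modalities
render grey/white and modality-unique structure keeps its colour.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .volume import ImageVolume, write_volume


def _norm01(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        if hi != 0:
            return np.ones_like(img)
        warnings.warn("constant-zero channel rendered black")
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def fuse_overlay(pat_slice: np.ndarray, rmri_slice: np.ndarray) -> np.ndarray:
    """8-bit RGB overlay: PAT -> magenta channels, MRI -> green channel."""
    if pat_slice.shape != rmri_slice.shape:
        raise ValueError("overlay inputs must share a grid")
    p = _norm01(pat_slice)
    m = _norm01(rmri_slice)
    rgb = np.stack([p, m, p], axis=-1)
    return np.round(rgb * 255.0).astype(np.uint8)


def save_overlay_png(pat_slice: np.ndarray, rmri_slice: np.ndarray, path: str) -> None:
    Image.fromarray(fuse_overlay(pat_slice, rmri_slice), mode="RGB").save(path)


def mip_panels(vol: ImageVolume) -> dict[str, np.ndarray]:
    """Orthogonal maximum-intensity projections (static 3-D views)."""
    return {
        "axial": vol.data.max(axis=0),
        "coronal": vol.data.max(axis=1),
        "sagittal": vol.data.max(axis=2),
    }


@dataclass
class ReportInputs:
    """Artifacts the bundle is built from; missing entries raise by name."""

    pat_reference: ImageVolume | None = None
    registered_mri: ImageVolume | None = None
    transforms: list[dict] = field(default_factory=list)
    registration_table: pd.DataFrame | None = None
    axial_table: pd.DataFrame | None = None
    so2_volume: ImageVolume | None = None
    chromophore_volumes: dict[str, ImageVolume] = field(default_factory=dict)
    summary_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)


def format_mean_std(values) -> str:
    """Table-style 'mean ± std' with 4 decimals."""
    arr = np.asarray(list(values), dtype=float)
    return f"{arr.mean():.4f} ± {arr.std(ddof=0):.4f}"


def build_report(inputs: ReportInputs, out_dir: str, overlay_slices: int = 8) -> dict:
    """Write the self-contained report bundle; returns a manifest dict.

    Bundle contents: transforms JSON, metrics CSVs, overlay PNG stack,
    fused NIfTI volumes, config echo and a plain-text log, all with
    deterministic names.
    """
    missing = []
    if inputs.pat_reference is None:
        missing.append("transverse registration (pat_reference)")
    if inputs.registered_mri is None:
        missing.append("transverse registration (registered_mri)")
    if inputs.registration_table is None:
        missing.append("metrics (registration_table)")
    if missing:
        raise ValueError("missing stage artifacts: " + "; ".join(missing))
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"files": []}

    def _record(name: str) -> str:
        manifest["files"].append(name)
        return os.path.join(out_dir, name)

    with open(_record("transforms.json"), "w") as fh:
        json.dump(inputs.transforms, fh, indent=2)
    inputs.registration_table.to_csv(_record("registration_report.csv"), index=False)
    if inputs.axial_table is not None:
        inputs.axial_table.to_csv(_record("axial_report.csv"), index=False)
    for name, df in inputs.summary_tables.items():
        df.to_csv(_record(f"{name}.csv"), index=False)

    write_volume(inputs.registered_mri, _record("rmri.nii.gz"))
    write_volume(inputs.pat_reference, _record("pat_reference.nii.gz"))
    if inputs.so2_volume is not None:
        write_volume(inputs.so2_volume, _record("so2.nii.gz"))
    for name, vol in inputs.chromophore_volumes.items():
        write_volume(vol, _record(f"conc_{name}.nii.gz"))

    n = inputs.pat_reference.n_slices
    picks = np.unique(np.linspace(0, n - 1, min(overlay_slices, n)).astype(int))
    os.makedirs(os.path.join(out_dir, "overlays"), exist_ok=True)
    for k in picks:
        name = f"overlays/overlay_{k:03d}.png"
        save_overlay_png(inputs.pat_reference.data[k], inputs.registered_mri.data[k],
                         os.path.join(out_dir, name))
        manifest["files"].append(name)

    for view, img in mip_panels(inputs.pat_reference).items():
        name = f"overlays/mip_{view}.png"
        arr = np.round(_norm01(img) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(os.path.join(out_dir, name))
        manifest["files"].append(name)

    with open(_record("config_echo.json"), "w") as fh:
        json.dump(inputs.config_echo, fh, indent=2, default=str)
    with open(_record("run.log"), "w") as fh:
        fh.write("\n".join(inputs.log_lines) + "\n")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
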