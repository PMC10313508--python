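"""End-to-end workflow: simulate -> preprocess -> axial -> transverse ->
unmix -> evaluate -> report.

Each stage is a thin call into the corresponding module; this file only
wires them together, carries provenance (seed, config echo, per-stage log)
and assembles the evaluation tables.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import axial as axial_mod
from . import metrics as metrics_mod
from . import phantom as phantom_mod
from . import preprocess as pre_mod
from . import report as report_mod
from . import transverse as trans_mod
from . import unmix as unmix_mod
from .config import PipelineConfig
from .transforms import RigidTransform2D
from .volume import (BinaryMask, ImageVolume, Modality, MultispectralStack,
                     read_volume, write_volume)


@dataclass
class SimulatedDataset:
    """In-memory phantom dataset with its ground truth."""

    mri: ImageVolume  # misaligned, as 'acquired'
    pat: MultispectralStack
    extinction: unmix_mod.ExtinctionTable
    markers: list[dict]  # {mri_z_mm, roi_center_px, roi_radius_px}
    scene: phantom_mod.PhantomScene
    misalignment: phantom_mod.MisalignmentModel
    mri_true: ImageVolume
    truth_masks_pat: tuple[BinaryMask, BinaryMask, BinaryMask]
    truth_masks_mri: tuple[BinaryMask, BinaryMask, BinaryMask]
    truth_concentrations: dict[str, np.ndarray]


def simulate_dataset(cfg: PipelineConfig) -> SimulatedDataset:
    """Render the paired phantom volumes described by the config."""
    sc = cfg.scene
    scene = phantom_mod.default_scene(seed=cfg.seed, z_extent_mm=sc.z_extent_mm,
                                      marker_spacing_mm=sc.marker_spacing_mm,
                                      n_markers=sc.n_markers,
                                      with_markers=sc.with_markers)
    mri_grid = tuple(cfg.mri.grid)
    mri_spacing = (cfg.mri.slice_spacing_mm, 0.1, 0.1)
    mri_true = phantom_mod.render_mri(scene, mri_grid, mri_spacing,
                                      noise_sigma=cfg.mri.noise_sigma)
    model = phantom_mod.random_misalignment(
        mri_true.n_slices, seed=cfg.seed + 1,
        global_translation_mm=cfg.misalignment.global_translation_mm,
        global_rotation_deg=cfg.misalignment.global_rotation_deg,
        jitter_translation_mm=cfg.misalignment.jitter_translation_mm,
        jitter_rotation_deg=cfg.misalignment.jitter_rotation_deg,
        axial_offset_mm=cfg.misalignment.axial_offset_mm,
        max_translation_mm=cfg.misalignment.max_translation_mm,
        max_rotation_deg=cfg.misalignment.max_rotation_deg)
    mri_mis = phantom_mod.apply_misalignment(mri_true, model)

    if cfg.unmixing.extinction_csv:
        table = unmix_mod.ExtinctionTable.from_csv(cfg.unmixing.extinction_csv)
    else:
        table = unmix_mod.demo_table(wavelengths_nm=list(cfg.pat.wavelengths_nm))
    pat_grid = tuple(cfg.pat.grid)
    pat_spacing = (cfg.pat.slice_spacing_mm, 0.1, 0.1)
    pat = phantom_mod.render_pat(scene, table, list(cfg.pat.wavelengths_nm),
                                 pat_grid, pat_spacing,
                                 marker_axial_sigma_mm=cfg.pat.marker_axial_sigma_mm,
                                 noise_sigma=cfg.pat.noise_sigma)
    n_pat = pat.shape[0]
    truth_pat = phantom_mod.ground_truth_masks(scene, pat_grid, pat_spacing, n_pat)
    truth_mri = phantom_mod.ground_truth_masks(scene, mri_grid, mri_spacing,
                                               mri_true.n_slices)
    conc = phantom_mod.chromophore_fields(scene, pat_grid, pat_spacing, n_pat)

    # marker bookkeeping: where each marker appears in each modality
    markers = []
    dy, dx = pat_spacing[1], pat_spacing[2]
    ny, nx = pat_grid
    mri_pos = mri_mis.slice_positions_mm()
    for m in scene.markers:
        my, mx = scene.marker_position_yx(m)
        row = my / dy + (ny - 1) / 2.0
        col = mx / dx + (nx - 1) / 2.0
        k = int(np.argmin(np.abs(mri_pos - (m.z_mm - model.axial_offset_mm))))
        markers.append({
            "mri_z_mm": float(mri_pos[k]),
            "roi_center_px": [float(row), float(col)],
            "roi_radius_px": float(m.diameter_mm / 2.0 / dy + 2.0),
        })
    return SimulatedDataset(mri_mis, pat, table, markers, scene, model,
                            mri_true, truth_pat, truth_mri, conc)


def save_dataset(data: SimulatedDataset, out_dir: str) -> None:
    """Write the simulated dataset (volumes as NIfTI, truth as JSON/NIfTI)."""
    os.makedirs(out_dir, exist_ok=True)
    write_volume(data.mri, os.path.join(out_dir, "mri.nii.gz"))
    for vol, lam in zip(data.pat.volumes, data.pat.wavelengths_nm):
        write_volume(vol, os.path.join(out_dir, f"pat_{int(lam)}nm.nii.gz"))
    data.extinction.to_csv(os.path.join(out_dir, "extinction.csv"))
    with open(os.path.join(out_dir, "markers.json"), "w") as fh:
        json.dump(data.markers, fh, indent=2)
    truth_dir = os.path.join(out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    write_volume(data.mri_true, os.path.join(truth_dir, "mri_true.nii.gz"))
    for name, mask in zip(("body", "tumor", "tumor_core"), data.truth_masks_pat):
        write_volume(mask, os.path.join(truth_dir, f"{name}_pat.nii.gz"))
    transforms = [t.to_dict() for t in data.misalignment.per_slice_transforms]
    with open(os.path.join(truth_dir, "true_transforms.json"), "w") as fh:
        json.dump({"axial_offset_mm": data.misalignment.axial_offset_mm,
                   "per_slice": transforms}, fh, indent=2)
    for name, arr in data.truth_concentrations.items():
        vol = ImageVolume(arr, data.pat.spacing, data.pat.origin, Modality.MAP)
        write_volume(vol, os.path.join(truth_dir, f"conc_{name}.nii.gz"))


@dataclass
class PipelineResult:
    offset_mm: float
    pairing: np.ndarray
    records: list[trans_mod.SliceRegistrationRecord]
    registered_mri: ImageVolume
    registration_table: pd.DataFrame
    axial_table: pd.DataFrame
    maps: unmix_mod.ChromophoreMaps | None
    so2_map: unmix_mod.SO2Map | None
    summary: dict[str, str]
    report_dir: str | None
    truth_table: pd.DataFrame | None = None


def _warp_mask(mask_slice: np.ndarray, t: RigidTransform2D,
               spacing, origin) -> np.ndarray:
    w = trans_mod.apply_transform(mask_slice.astype(np.float64), t, spacing, origin)
    return w > 0.5


def _norm01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


def run_pipeline(cfg: PipelineConfig, data: SimulatedDataset | None = None,
                 write_report: bool = True) -> PipelineResult:
    """Run preprocess -> axial -> transverse -> unmix -> evaluate -> report."""
    log: list[str] = []
    t_start = time.time()

    def stage(msg: str) -> None:
        log.append(f"[{time.time() - t_start:7.2f}s] {msg}")

    if data is None:
        stage("simulate: rendering phantom dataset")
        data = simulate_dataset(cfg)

    # ---- preprocess -------------------------------------------------------
    stage("preprocess: MRI wiener+segment+resize, PAT nonneg+segment")
    params = pre_mod.PreprocessParams(
        wiener_window=tuple(cfg.preprocess.wiener_window),
        morph_close_radius_px=cfg.preprocess.morph_close_radius_px,
        seg_method=cfg.preprocess.seg_method)
    mri_p, mri_mask = pre_mod.preprocess_mri(data.mri, params)
    pat_nn = MultispectralStack([pre_mod.enforce_nonneg(v) for v in data.pat.volumes],
                                data.pat.wavelengths_nm)
    pat_ref = ImageVolume(pat_nn.as_array().mean(axis=0), pat_nn.spacing,
                          pat_nn.origin, Modality.PAT)
    pat_ref, pat_mask = pre_mod.preprocess_pat(pat_ref, params)

    # ---- axial registration ----------------------------------------------
    stage("axial: marker profiles, Gaussian fits, slice pairing")
    marker_args = [(axial_mod.MarkerROI(tuple(m["roi_center_px"]), m["roi_radius_px"]),
                    float(m["mri_z_mm"])) for m in data.markers]
    if marker_args:
        offset, pairing, recs = axial_mod.register_axial(pat_ref, mri_p, marker_args)
        axial_table = pd.DataFrame(recs)
    else:
        offset = 0.0
        pairing = axial_mod.align_stacks(pat_ref, mri_p, 0.0)
        axial_table = pd.DataFrame(
            columns=["marker", "mu_mm", "sigma_mm", "rmse", "pat_slice", "offset_mm"])

    # ---- transverse registration -----------------------------------------
    stage(f"transverse: {cfg.registration.mode} {cfg.registration.model} MI registration")
    oc = cfg.registration.optimizer
    opt = trans_mod.OptimizerParams(
        growth_factor=oc.growth_factor, epsilon=oc.epsilon,
        initial_radius=oc.initial_radius, max_iterations=oc.max_iterations,
        seed=cfg.seed, n_starts=oc.n_starts, init=oc.init, n_bins=oc.n_bins)
    records = trans_mod.register_volume_2d(pat_ref, mri_p, pairing,
                                           cfg.registration.model, opt,
                                           pat_mask.data, mri_mask.data)
    rmri = trans_mod.registered_volume(mri_p, records)

    # ---- evaluation -------------------------------------------------------
    stage("metrics: per-slice DSC / SSIM before and after")
    sp2 = (mri_p.spacing[1], mri_p.spacing[2])
    org2 = (mri_p.origin[1], mri_p.origin[2])
    rows = []
    for rec in records:
        k, j = rec.mri_slice, rec.pat_slice
        t = rec.result.transform
        mask_before = mri_mask.data[k]
        mask_after = _warp_mask(mask_before, t, sp2, org2)
        dsc_before = metrics_mod.dice(pat_mask.data[j], mask_before)
        dsc_after = metrics_mod.dice(pat_mask.data[j], mask_after)
        # SSIM on per-slice min-max normalised images (L = 1): the two
        # modalities' native intensity scales are unrelated
        sp = metrics_mod.SSIMParams(L=1.0)
        pat_n = _norm01(pat_ref.data[j])
        ssim_before = metrics_mod.ssim_global(pat_n, _norm01(mri_p.data[k]), sp)
        ssim_after = metrics_mod.ssim_global(pat_n, _norm01(rec.result.registered), sp)
        rows.append({
            "mri_slice": k, "pat_slice": j,
            "tx_mm": t.tx, "ty_mm": t.ty, "theta_deg": t.theta_deg,
            "scale": t.scale, "mi_initial": rec.result.mi_initial,
            "mi_final": rec.result.mi_final, "iterations": rec.result.iterations,
            "dsc_before": dsc_before, "dsc_after": dsc_after,
            "ssim_before": ssim_before, "ssim_after": ssim_after,
        })
    reg_table = pd.DataFrame(rows)
    summary = {
        "dsc_after": report_mod.format_mean_std(reg_table["dsc_after"]),
        "dsc_before": report_mod.format_mean_std(reg_table["dsc_before"]),
        "ssim_after": report_mod.format_mean_std(reg_table["ssim_after"]),
        "axial_offset_mm": f"{offset:.4f}",
    }

    truth_table = None
    if data.misalignment is not None:
        errs = []
        for rec in records:
            inj = data.misalignment.per_slice_transforms[rec.mri_slice]
            e = rec.result.transform.compose(inj)  # ideally identity
            errs.append({"mri_slice": rec.mri_slice, "err_tx_mm": e.tx,
                         "err_ty_mm": e.ty, "err_theta_deg": e.theta_deg})
        truth_table = pd.DataFrame(errs)

    # ---- unmixing ---------------------------------------------------------
    maps = so2m = None
    unmix_tables: dict[str, pd.DataFrame] = {}
    if cfg.unmixing.enabled:
        stage(f"unmix: {cfg.unmixing.mode} over {len(pat_nn)} wavelengths")
        maps = unmix_mod.unmix(pat_nn, data.extinction, cfg.unmixing.mode)
        so2m = unmix_mod.so2(maps)
        body, tumor, core = data.truth_masks_pat
        so2_rows = []
        for name, mask in (("tumor", tumor), ("tumor_core", core), ("body", body)):
            sel = mask.data & so2m.valid.data
            if sel.any():
                so2_rows.append({"roi": name,
                                 "mean_so2": float(so2m.values.data[sel].mean()),
                                 "volume_mm3": metrics_mod.mask_volume(mask)})
        unmix_tables["so2_quantification"] = pd.DataFrame(so2_rows)

    # ---- report -----------------------------------------------------------
    report_dir = None
    if write_report:
        stage("report: writing bundle")
        report_dir = cfg.output_dir
        pat_paired = ImageVolume(pat_ref.data[pairing], rmri.spacing, rmri.origin,
                                 Modality.PAT)
        inputs = report_mod.ReportInputs(
            pat_reference=pat_paired, registered_mri=rmri,
            transforms=[{"mri_slice": r.mri_slice, "pat_slice": r.pat_slice,
                         **r.result.transform.to_dict()} for r in records],
            registration_table=reg_table, axial_table=axial_table,
            so2_volume=so2m.values if so2m else None,
            chromophore_volumes={n: maps[n] for n in maps.chromophores} if maps else {},
            summary_tables={**unmix_tables,
                            "summary": pd.DataFrame([summary])},
            config_echo={"config": cfg.to_dict(), "seed": cfg.seed},
            log_lines=log)
        report_mod.build_report(inputs, report_dir)

    return PipelineResult(offset, pairing, records, rmri, reg_table, axial_table,
                          maps, so2m, summary, report_dir, truth_table)


def register_3d_variant(cfg: PipelineConfig, data: SimulatedDataset,
                        model: str = "rigid") -> tuple[pd.DataFrame, trans_mod.VolumeRegistrationResult]:
    """Whole-volume 3-D registration of the same dataset, for comparison.

    The MRI stack is put on the PAT axial grid by nearest-slice duplication
    (its native sampling is coarser), one global transform is estimated, and
    the same per-slice mask DSC table is produced so 2-D and 3-D numbers are
    directly comparable.
    """
    params = pre_mod.PreprocessParams(
        wiener_window=tuple(cfg.preprocess.wiener_window),
        morph_close_radius_px=cfg.preprocess.morph_close_radius_px)
    mri_p, mri_mask = pre_mod.preprocess_mri(data.mri, params)
    pat_nn = MultispectralStack([pre_mod.enforce_nonneg(v) for v in data.pat.volumes],
                                data.pat.wavelengths_nm)
    pat_ref = ImageVolume(pat_nn.as_array().mean(axis=0), pat_nn.spacing,
                          pat_nn.origin, Modality.PAT)
    pat_ref, pat_mask = pre_mod.preprocess_pat(pat_ref, params)
    # evaluate on the MRI slice positions: pick nearest PAT slice per MRI slice
    pairing = axial_mod.align_stacks(pat_ref, mri_p, 0.0)
    pat_sub = ImageVolume(pat_ref.data[pairing], mri_p.spacing, mri_p.origin,
                          Modality.PAT)
    oc = cfg.registration.optimizer
    opt = trans_mod.OptimizerParams(
        growth_factor=oc.growth_factor, epsilon=oc.epsilon,
        initial_radius=oc.initial_radius, max_iterations=oc.max_iterations,
        seed=cfg.seed, n_starts=oc.n_starts, init=oc.init, n_bins=oc.n_bins)
    res = trans_mod.register_volume_3d(pat_sub, mri_p, model, opt,
                                       pat_mask=pat_mask.data[pairing],
                                       mri_mask=mri_mask.data)
    sp2 = (mri_p.spacing[1], mri_p.spacing[2])
    org2 = (mri_p.origin[1], mri_p.origin[2])
    mask_vol = ImageVolume(mri_mask.data.astype(np.float64), mri_p.spacing, mri_p.origin)
    from .transforms import apply_transform_3d
    warped_mask = apply_transform_3d(mask_vol.data, res.transform, mri_p.spacing,
                                     mri_p.origin) > 0.5
    rows = []
    for k, j in enumerate(pairing):
        rows.append({"mri_slice": k, "pat_slice": int(j),
                     "dsc_before": metrics_mod.dice(pat_mask.data[j], mri_mask.data[k]),
                     "dsc_after": metrics_mod.dice(pat_mask.data[j], warped_mask[k]),
                     "ssim_after": metrics_mod.ssim_global(
                         _norm01(pat_ref.data[j]), _norm01(res.registered.data[k]),
                         metrics_mod.SSIMParams(L=1.0))})
    return pd.DataFrame(rows), res
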