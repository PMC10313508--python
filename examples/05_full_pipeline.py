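"""The whole workflow in one call, plus the 2-D-vs-3-D comparison.

Simulates the misaligned phantom (per-slice jitter + global motion + 1.2 mm
axial offset), runs preprocessing, marker-based axial pairing, per-slice MI
registration, unmixing and evaluation, writes the report bundle, and then
registers the same dataset with a single global 3-D transform to show why
per-slice 2-D registration wins when the motion is not purely global.

Equivalent CLI:  pamreg pipeline --config <cfg.yaml>
"""

import pamreg as pr

cfg = pr.PipelineConfig()
cfg.seed = 5
cfg.scene.z_extent_mm = 8.0
cfg.output_dir = "scratch/example_report"

result = pr.run_pipeline(cfg)
print(f"report bundle: {result.report_dir}")
print(f"axial offset recovered: {result.offset_mm:.3f} mm "
      f"(injected {cfg.misalignment.axial_offset_mm})")
print(f"body-mask DSC, per-slice 2-D rigid: {result.summary['dsc_after']}"
      f"  (before registration: {result.summary['dsc_before']})")

data = pr.simulate_dataset(cfg)
df3, res3 = pr.register_3d_variant(cfg, data, "rigid")
print(f"body-mask DSC, one global 3-D rigid: "
      f"{df3['dsc_after'].mean():.4f} ± {df3['dsc_after'].std(ddof=0):.4f}")
print("per-slice 2-D registration outperforms the single 3-D fit because the "
      "slice-to-slice jitter has no volumetric rigid explanation.")
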