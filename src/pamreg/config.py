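"""Pipeline configuration: a validated, declarative description of a run.

Configs load from YAML or JSON.  Unknown keys are rejected with the full
field path so a typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
import json
import typing
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    pass


def _build(cls, d: dict, path: str):
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(d).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        ftype = hints.get(f.name, f.type)
        if dataclasses.is_dataclass(ftype) and isinstance(v, dict):
            v = _build(ftype, v, f"{path}.{f.name}")
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class SceneConfig:
    z_extent_mm: float = 12.0
    marker_spacing_mm: float = 10.0
    n_markers: int | None = None
    with_markers: bool = True


@dataclass
class MRIConfig:
    noise_sigma: float = 2.0
    slice_spacing_mm: float = 1.0
    grid: list = field(default_factory=lambda: [250, 250])


@dataclass
class PATConfig:
    noise_sigma: float = 0.0
    slice_spacing_mm: float = 0.3
    grid: list = field(default_factory=lambda: [300, 300])
    wavelengths_nm: list = field(default_factory=lambda: [700.0, 730.0, 760.0, 800.0, 850.0])
    marker_axial_sigma_mm: float = 1.3


@dataclass
class MisalignmentConfig:
    global_translation_mm: float = 2.0
    global_rotation_deg: float = 5.0
    jitter_translation_mm: float = 0.4
    jitter_rotation_deg: float = 1.0
    axial_offset_mm: float = 1.2
    max_translation_mm: float = 3.0
    max_rotation_deg: float = 10.0


@dataclass
class PreprocessConfig:
    wiener_window: list = field(default_factory=lambda: [3, 3])
    morph_close_radius_px: int = 2
    seg_method: str = "otsu_cc"


@dataclass
class OptimizerConfig:
    growth_factor: float = 1.05
    epsilon: float = 1.5e-6
    initial_radius: float = 6.3e-3
    max_iterations: int = 100
    n_starts: int = 1
    init: str = "moments"
    n_bins: int = 64


@dataclass
class RegistrationConfig:
    model: str = "rigid"  # rigid | similarity
    mode: str = "2d"  # 2d | 3d
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self) -> None:
        if self.model not in ("rigid", "similarity"):
            raise ConfigError(f"registration.model must be rigid|similarity, got {self.model!r}")
        if self.mode not in ("2d", "3d"):
            raise ConfigError(f"registration.mode must be 2d|3d, got {self.mode!r}")


@dataclass
class UnmixingConfig:
    enabled: bool = True
    mode: str = "nnls"
    extinction_csv: str | None = None  # None: bundled demo (synthetic) table


@dataclass
class PipelineConfig:
    seed: int = 0
    dataset_dir: str = "dataset"
    output_dir: str = "report"
    scene: SceneConfig = field(default_factory=SceneConfig)
    mri: MRIConfig = field(default_factory=MRIConfig)
    pat: PATConfig = field(default_factory=PATConfig)
    misalignment: MisalignmentConfig = field(default_factory=MisalignmentConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    unmixing: UnmixingConfig = field(default_factory=UnmixingConfig)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        return _build(PipelineConfig, d, "config")

    @staticmethod
    def from_file(path: str) -> "PipelineConfig":
        with open(path) as fh:
            if path.endswith(".json"):
                d = json.load(fh)
            else:
                d = yaml.safe_load(fh)
        return PipelineConfig.from_dict(d or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
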