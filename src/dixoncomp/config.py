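"""Pipeline configuration: a single YAML file mapped onto dataclasses.

Unknown keys are rejected so typos fail fast; every threshold that a
module exposes as a keyword argument has its default mirrored here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError
from .segmentation import RegistrationConfig

__all__ = ["PipelineConfig", "PhantomDefaults", "PreprocessConfig",
           "QAThresholds", "CohortConfig", "load_config"]


@dataclass
class PhantomDefaults:
    """Generator parameters shared by a synthetic cohort."""

    scale: float = 5.0
    vat_l: float = 3.73
    asat_l: float = 6.91
    lat_l: float = 1.66
    rat_l: float = 1.68
    lpt_l: float = 3.36
    rpt_l: float = 3.39
    bias_amplitude: float = 0.2
    noise_sd: float = 0.025
    # fractional spread of per-subject anatomical variation
    subject_spread: float = 1.0


@dataclass
class PreprocessConfig:
    noise_floor: float | None = None       # None: automatic
    pure_fat_threshold: float = 0.9
    bias_control_scale_mm: float = 60.0
    swap_water_plausibility: float = 0.2
    min_component_voxels: int = 50


@dataclass
class QAThresholds:
    tilt_threshold_deg: float = 5.0
    respiratory_threshold: float = 0.01
    outer_fov_rind_mm: float = 30.0
    shell_mm: float = 12.0
    min_void_ml: float = 5.0


@dataclass
class CohortConfig:
    n_subjects: int = 12
    n_atlases: int = 15
    #: run segmentation on accepted subjects (QA-only cohorts set False)
    segment: bool = True
    #: artifact kind -> number of subjects receiving it (one artifact each)
    artifacts: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    seed: int = 0
    vote_threshold: int = 5
    phantom: PhantomDefaults = field(default_factory=PhantomDefaults)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    qa: QAThresholds = field(default_factory=QAThresholds)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, "config")

    def to_dict(self) -> dict:
        return asdict(self)


_NESTED = {
    "phantom": PhantomDefaults,
    "preprocess": PreprocessConfig,
    "qa": QAThresholds,
    "registration": RegistrationConfig,
    "cohort": CohortConfig,
}


def _build(cls, data: dict, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        sub = _NESTED.get(f.name)
        if sub is not None and cls is PipelineConfig:
            kwargs[f.name] = _build(sub, data[f.name], f"{path}.{f.name}")
        elif f.name in ("shrink_factors", "smoothing_sigmas"):
            kwargs[f.name] = tuple(data[f.name])
        else:
            kwargs[f.name] = data[f.name]
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a YAML config file; missing file fields keep their defaults."""
    text = Path(path).read_text()
    return PipelineConfig.from_dict(yaml.safe_load(text) or {})
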