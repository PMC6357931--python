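"""Pipeline configuration: one structured object covering every stage.

Defaults mirror the acquisition constants (15 fps, 0.2 mm/pixel) and the
satisfaction band (500..1500 px); everything else is an engineering
default documented in the methods note. Unknown keys are rejected at load
time so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .refinement import (DEFAULT_D_CENTER_PX, DEFAULT_D_EDGE_PX,
                         DEFAULT_TH_STEP)
from .registration import RegistrationSettings
from .segmentation import DEFAULT_SCALES_PX, DEFAULT_THRESHOLD
from .timing import (DEFAULT_DEGREE, DEFAULT_KAPPA, DEFAULT_N_BASE,
                     DEFAULT_PERSIST, DEFAULT_RISE_FRAC)

__all__ = ["SegmentationConfig", "RefinementConfig", "TimingConfig",
           "VelocityConfig", "PipelineConfig"]


@dataclass
class SegmentationConfig:
    th: float = DEFAULT_THRESHOLD
    scales_px: tuple[float, ...] = DEFAULT_SCALES_PX

    def validate(self) -> None:
        if not 0 < self.th < 1:
            raise ValueError("segmentation.th must be in (0, 1)")
        if not self.scales_px or min(self.scales_px) < 0.5:
            raise ValueError("segmentation.scales_px must be >= 0.5 px")


@dataclass
class RefinementConfig:
    enabled: bool = True
    sat_lower_px: float = 500.0
    sat_upper_px: float = 1500.0
    reference_spacing_mm: float = 0.2
    th_step: float = DEFAULT_TH_STEP
    d_edge_px: float = DEFAULT_D_EDGE_PX
    d_center_px: float = DEFAULT_D_CENTER_PX
    max_iter: int = 10

    def validate(self) -> None:
        if not 0 <= self.sat_lower_px < self.sat_upper_px:
            raise ValueError("need 0 <= sat_lower_px < sat_upper_px")
        if self.max_iter < 0:
            raise ValueError("refinement.max_iter must be >= 0")
        if self.th_step <= 0:
            raise ValueError("refinement.th_step must be positive")


@dataclass
class TimingConfig:
    degree: int = DEFAULT_DEGREE
    t_max_mode: str = "rate_threshold"
    kappa: float = DEFAULT_KAPPA
    n_base: int = DEFAULT_N_BASE
    rise_frac: float = DEFAULT_RISE_FRAC
    persist: int = DEFAULT_PERSIST

    def validate(self) -> None:
        if self.degree < 1:
            raise ValueError("timing.degree must be >= 1")
        if self.t_max_mode not in ("rate_threshold", "first_max"):
            raise ValueError("timing.t_max_mode must be rate_threshold or "
                             "first_max")
        if not 0 < self.kappa < 1:
            raise ValueError("timing.kappa must be in (0, 1)")


@dataclass
class VelocityConfig:
    mode: str = "endpoint"               # or "increments"
    use_registered_geometry: bool = False

    def validate(self) -> None:
        if self.mode not in ("endpoint", "increments"):
            raise ValueError("velocity.mode must be endpoint or increments")


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    registration: RegistrationSettings = field(
        default_factory=RegistrationSettings.coarse)
    timing: TimingConfig = field(default_factory=TimingConfig)
    velocity: VelocityConfig = field(default_factory=VelocityConfig)
    fps_override: float | None = None
    spacing_override_mm: float | None = None
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for sub in (self.segmentation, self.refinement, self.timing,
                    self.velocity):
            sub.validate()
        if self.fps_override is not None and self.fps_override <= 0:
            raise ValueError("fps_override must be positive")
        if (self.spacing_override_mm is not None
                and self.spacing_override_mm <= 0):
            raise ValueError("spacing_override_mm must be positive")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config section or key: {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                names = {f.name for f in dataclasses.fields(current)}
                for sub_key, sub_val in value.items():
                    if sub_key not in names:
                        raise ValueError(
                            f"unknown config key: {key}.{sub_key!r}")
                    if isinstance(sub_val, list):
                        sub_val = tuple(sub_val)
                    setattr(current, sub_key, sub_val)
            else:
                setattr(cfg, key, value)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
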