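"""Run configuration: every tunable threshold in one validated, serializable place."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class MspConfig(BaseModel):
    n_bins: int = Field(64, ge=2)
    voi_half_fraction: float = Field(0.2, gt=0, le=0.5)
    air_threshold: float | None = None
    skull_threshold: float = 200.0


class DetectionConfig(BaseModel):
    t_mean: float = Field(6.0, ge=0)
    t_sd: float = Field(6.0, ge=0)
    t_peak: float = Field(0.05, ge=0)
    z_margin: float = Field(2.0, ge=0)
    min_finding_ml: float = Field(0.5, ge=0)


class SegmentationConfig(BaseModel):
    dwi_ratio_threshold: float = Field(3.0, gt=1)
    dwi_min_component_ml: float = Field(1.0, ge=0)
    periventricular_mm: float = Field(10.0, ge=0)
    csf_dilate_mm: float = Field(4.0, ge=0)


class MappingConfig(BaseModel):
    mip_width_mm: float = Field(10.0, gt=0)
    outline_lower: float = 60.0
    outline_upper: float = 200.0
    extended: bool = False


class RunConfig(BaseModel):
    """Top-level configuration; round-trips losslessly through YAML."""

    seed: int = 0
    verbosity: int = Field(1, ge=0, le=2)
    msp: MspConfig = Field(default_factory=MspConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    mapping: MappingConfig = Field(default_factory=MappingConfig)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))
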