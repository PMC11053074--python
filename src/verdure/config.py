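"""Pipeline configuration: one YAML-loadable block for all three stages.

Defaults mirror the reference operating point: 256x256 inputs, embed dim
C = 96 with block depths (2, 4, 2, 2), Adam with batch size 4, 150/100/100
epochs at learning rates 5e-5 / 5e-5 / 1e-5, blur threshold 0.5, greenery
area threshold 0.4.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .detector import DetectorConfig

__all__ = ["StageTraining", "PipelineConfig"]


@dataclass
class StageTraining:
    epochs: int
    lr: float


@dataclass
class PipelineConfig:
    input_size: int = 256
    blur_threshold: float = 0.5
    area_threshold: float = 0.4
    mask_threshold: float = 0.5
    batch_size: int = 4
    optimizer: str = "adam"
    wait_s: float = 60.0          # live mode; batch/test runs pass 0
    max_reshoots: int = 3
    stage1: StageTraining = field(default_factory=lambda: StageTraining(150, 5e-5))
    stage2: StageTraining = field(default_factory=lambda: StageTraining(100, 5e-5))
    stage3: StageTraining = field(default_factory=lambda: StageTraining(100, 1e-5))
    backbone: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)

    def backbone_config(self) -> BackboneConfig:
        kwargs = dict(self.backbone)
        for key in ("depths", "heads"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return BackboneConfig(**kwargs)

    def detector_config(self) -> DetectorConfig:
        kwargs = dict(self.detector)
        for key in ("anchor_scales", "aspect_ratios"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return DetectorConfig(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("stage1", "stage2", "stage3"):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = StageTraining(**doc[key])
        return cls(**doc)
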