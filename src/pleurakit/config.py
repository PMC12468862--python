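"""Serializable run configuration.

A ``RunConfig`` captures every stage parameter plus the run seed so a
detection or experiment run can be reproduced bit-for-bit from its saved
YAML (the backends shipped with the package are deterministic).  The
effective configuration is dumped next to every run's outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .enhancement import EnhanceConfig, SobelConfig
from .evalkit import PipelineConfig, TrainConfig
from .preprocess import AHEParams, BT601_WEIGHTS, MorphParams
from .segmentation import SegmentationParams


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "runs"
    log_level: str = "INFO"
    grayscale_weights: tuple[float, float, float] = BT601_WEIGHTS
    binarize_threshold: float = 0.5
    equalize_before_binarize: bool = False
    ahe: AHEParams = field(default_factory=AHEParams)
    morph: MorphParams = field(default_factory=MorphParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(segmentation=self.segmentation, enhance=self.enhance)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        # tuples -> lists for clean YAML round-trips
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(data), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "grayscale_weights" in kwargs:
            kwargs["grayscale_weights"] = tuple(kwargs["grayscale_weights"])
        if "ahe" in kwargs:
            kwargs["ahe"] = AHEParams(**kwargs["ahe"])
        if "morph" in kwargs:
            m = dict(kwargs["morph"])
            m["sequence"] = tuple(m.get("sequence", ("close", "open")))
            kwargs["morph"] = MorphParams(**m)
        if "segmentation" in kwargs:
            s = dict(kwargs["segmentation"])
            s["output_size"] = tuple(s.get("output_size", (227, 227)))
            kwargs["segmentation"] = SegmentationParams(**s)
        if "enhance" in kwargs:
            e = dict(kwargs["enhance"])
            if "sobel" in e:
                e["sobel"] = SobelConfig(**e["sobel"])
            if "clahe_params" in e:
                e["clahe_params"] = AHEParams(**e["clahe_params"])
            kwargs["enhance"] = EnhanceConfig(**e)
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        return cls(**kwargs)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj
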