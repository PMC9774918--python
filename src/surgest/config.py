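"""Run configuration: one serialisable object tying every stage together.

Training defaults (epochs 15/30/30, learning rates 1e-4/1e-5/1e-5, batch 10)
follow the reference protocol; synthetic desk-scale runs override them.
YAML round-trips exactly (write -> read -> identical dataclasses).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .decomposition import DecompositionConfig
from .st import EncoderConfig, TrainConfig


def _default_decomposition() -> DecompositionConfig:
    # synthetic trials are rendered directly on the 5 fps timeline
    return DecompositionConfig(width=64, height=64, subsample_factor=1)


@dataclass
class RunConfig:
    task: str = "PT"
    variant: str = "C3DTrans"
    budget: float = 1.0
    k_folds: int = 5
    seed: int = 0
    n_trials: int = 40
    out_dir: str = "runs"
    deterministic: bool = True
    volume_stride: int = 1
    pretext_stride: int = 1
    clip_stride: int = 1
    decomposition: DecompositionConfig = field(default_factory=_default_decomposition)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (("decomposition", DecompositionConfig),
                         ("encoder", EncoderConfig),
                         ("training", TrainConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def override(self, **kwargs) -> "RunConfig":
        """New config with non-None keyword overrides applied (CLI flags)."""
        data = self.to_dict()
        for key, value in kwargs.items():
            if value is not None:
                data[key] = value
        return RunConfig.from_dict(data)
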