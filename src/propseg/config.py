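"""Model architecture configuration shared by the context and segmentation nets."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml

__all__ = ["ModelConfig", "desk_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the propagation segmenter.

    ``depth`` encoder levels with per-level ``channels`` and convolution
    ``kernels`` (decreasing kernel sizes give the context paths different
    fields of view); ``context_enabled`` switches the context-conditioning
    pathway on (off reproduces the no-context ablation); ``aux_weight``
    scales the deep-supervision auxiliary loss; ``threshold`` binarizes
    probability maps; ``direction`` is the propagation order through the
    stack ("down" = top slice first).
    """

    image_size: int = 128
    depth: int = 4
    channels: tuple = (8, 16, 32, 64)
    kernels: tuple = (7, 5, 3, 3)
    context_enabled: bool = True
    aux_weight: float = 0.4
    threshold: float = 0.5
    direction: str = "down"
    seed: int = 0

    def validate(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.channels) != self.depth or len(self.kernels) != self.depth:
            raise ValueError("channels and kernels must have length == depth")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.image_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by 2^depth={2 ** self.depth}")
        if self.direction not in ("down", "up"):
            raise ValueError("direction must be 'down' or 'up'")
        return self

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("channels", "kernels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def replace(self, **kw):
        return replace(self, **kw)


def desk_config(**overrides) -> ModelConfig:
    """Small CPU-friendly architecture: 64x64 inputs, three levels."""
    cfg = ModelConfig(image_size=64, depth=3, channels=(8, 16, 32),
                      kernels=(7, 5, 3))
    return cfg.replace(**overrides).validate()
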