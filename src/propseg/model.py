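"""The full propagation segmenter: context net + segmentation net.

Both sub-networks are always constructed from the config seed in the same
order, so a model with the context pathway disabled carries exactly the same
segmentation-net weights as its context-enabled twin — the disabled variant
just routes all-zero context features, which makes the ablation a pure
on/off comparison.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import nn
from .config import ModelConfig
from .context_net import ContextInput, ContextNet
from .seg_net import SegNet, binarize

__all__ = ["PropSegModel"]


class PropSegModel(nn.Module):
    def __init__(self, config: ModelConfig, rng=None):
        super().__init__()
        config.validate()
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.context_net = ContextNet(config, rng)
        self.seg_net = SegNet(config, rng)

    def __call__(self, images: nn.Tensor, ctx_planes: nn.Tensor | None,
                 deep_supervision: bool = True):
        """images (N,1,H,W), ctx_planes (N,3,H,W) -> (logits, aux_logits|None).

        With the context pathway disabled, ctx_planes is ignored entirely and
        the segmentation net receives zero context features.
        """
        if self.config.context_enabled and ctx_planes is not None:
            feats = self.context_net(ctx_planes, deep_supervision=deep_supervision)
            return self.seg_net(images, feats.pyramid), feats.aux_logits
        return self.seg_net(images, None), None

    def predict_proba(self, image: np.ndarray, ctx: ContextInput) -> np.ndarray:
        """Foreground probability map for one slice (evaluation mode)."""
        self.eval()
        size = self.config.image_size
        img = nn.Tensor(np.asarray(image, dtype=np.float32)[None, None])
        planes = nn.Tensor(ctx.planes(size).astype(np.float32)[None])
        logits, _ = self(img, planes, deep_supervision=False)
        return nn.sigmoid(logits).data[0, 0].astype(np.float64)

    def predict_mask(self, image: np.ndarray, ctx: ContextInput) -> np.ndarray:
        return binarize(self.predict_proba(image, ctx), self.config.threshold)

    # ------------------------------------------------------------ checkpoints

    def save(self, weights_path, config_path=None):
        """Write weights as a single .npz plus the config as YAML."""
        weights_path = Path(weights_path)
        np.savez(weights_path, **self.state_dict())
        if config_path is None:
            config_path = weights_path.with_suffix(".yaml")
        self.config.to_yaml(config_path)

    @classmethod
    def load(cls, weights_path, config_path=None) -> "PropSegModel":
        weights_path = Path(weights_path)
        if config_path is None:
            config_path = weights_path.with_suffix(".yaml")
        model = cls(ModelConfig.from_yaml(config_path))
        with np.load(weights_path) as data:
            model.load_state_dict(dict(data))
        return model
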