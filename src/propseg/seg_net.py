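"""Encoder-decoder segmentation network with first-layer re-injection.

The encoder is ``depth`` conv -> batch-norm -> ReLU -> pool levels with
per-level kernel sizes; every level below the first additionally receives an
average-pooled copy of the first level's feature maps (re-injection of the
raw-image features, which counters the loss of fine structure with depth)
and, when context conditioning is enabled, the context pyramid level at the
matching scale. The decoder mirrors the encoder with ``depth`` upsampling
blocks, each a stride-2 transposed convolution followed by two convolutions,
fused with the corresponding encoder level through a skip connection. A 1x1
convolution head emits one logit per pixel; the sigmoid of that is the
foreground probability map, the same spatial size as the input slice.

When the context pathway is disabled the network keeps the identical weight
layout and simply receives all-zero context features, so the two variants
differ only in what flows through the context channels.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig

__all__ = ["SegNet", "binarize"]


class _ConvBNReLU(nn.Module):
    def __init__(self, c_in, c_out, k, rng):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, rng)
        self.bn = nn.BatchNorm2d(c_out)

    def __call__(self, x):
        return nn.relu(self.bn(self.conv(x)))


class _UpBlock(nn.Module):
    """Transposed-conv upsampling then two convs over the fused skip features."""

    def __init__(self, c_in, c_skip, c_out, rng):
        super().__init__()
        self.up = nn.ConvTranspose2d(c_in, c_out, 2, rng)
        self.conv1 = _ConvBNReLU(c_out + c_skip, c_out, 3, rng)
        self.conv2 = _ConvBNReLU(c_out, c_out, 3, rng)

    def __call__(self, x, skip):
        x = self.up(x)
        x = self.conv1(nn.concat([x, skip]))
        return self.conv2(x)


class SegNet(nn.Module):
    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        config.validate()
        self.config = config
        ch, ks = config.channels, config.kernels
        d = config.depth
        # encoder level 0 sees the image plus context level 0;
        # deeper levels see pooled features + re-injected level-0 features + context
        self.enc = [_ConvBNReLU(1 + ch[0], ch[0], ks[0], rng)]
        for lvl in range(1, d):
            c_in = ch[lvl - 1] + ch[0] + ch[lvl]
            self.enc.append(_ConvBNReLU(c_in, ch[lvl], ks[lvl], rng))
        self.dec = []
        c_prev = ch[d - 1]  # bottleneck channels (pooled deepest encoder level)
        for lvl in range(d - 1, -1, -1):
            self.dec.append(_UpBlock(c_prev, ch[lvl], ch[lvl], rng))
            c_prev = ch[lvl]
        self.head = nn.Conv2d(ch[0], 1, 1, rng)

    def _children(self):
        yield from self.enc
        yield from self.dec
        yield self.head

    def named_parameters(self, prefix=""):
        for i, m in enumerate(self.enc):
            yield from m.named_parameters(f"{prefix}enc.{i}.")
        for i, m in enumerate(self.dec):
            yield from m.named_parameters(f"{prefix}dec.{i}.")
        yield from self.head.named_parameters(f"{prefix}head.")

    def named_buffers(self, prefix=""):
        for i, m in enumerate(self.enc):
            yield from m.named_buffers(f"{prefix}enc.{i}.")
        for i, m in enumerate(self.dec):
            yield from m.named_buffers(f"{prefix}dec.{i}.")

    def _zero_pyramid(self, n: int, dtype):
        size, ch = self.config.image_size, self.config.channels
        return [nn.Tensor(np.zeros((n, ch[d], size >> d, size >> d), dtype=dtype))
                for d in range(self.config.depth)]

    def __call__(self, image: nn.Tensor, ctx_pyramid=None) -> nn.Tensor:
        """image: Tensor (N, 1, H, W); returns per-pixel logits (N, 1, H, W)."""
        n, _, h, w = image.data.shape
        if (h, w) != (self.config.image_size,) * 2:
            raise ValueError(f"input is {h}x{w}, model built for "
                             f"{self.config.image_size}x{self.config.image_size}")
        if ctx_pyramid is None:
            ctx_pyramid = self._zero_pyramid(n, image.data.dtype)
        skips = []
        x = self.enc[0](nn.concat([image, ctx_pyramid[0]]))
        first = x
        skips.append(x)
        for lvl in range(1, self.config.depth):
            pooled = nn.maxpool2d(x)
            reinject = nn.avgpool2d(first, 2 ** lvl)
            x = self.enc[lvl](nn.concat([pooled, reinject, ctx_pyramid[lvl]]))
            skips.append(x)
        x = nn.maxpool2d(x)  # bottleneck
        for blk, skip in zip(self.dec, reversed(skips)):
            x = blk(x, skip)
        return self.head(x)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map to a {0,1} mask (strictly greater-than)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    return (np.asarray(prob) > threshold).astype(np.uint8)
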