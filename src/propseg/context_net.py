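"""Context feature extraction: the sequence-conditioning half of the model.

For slice i the context is the triple (previous slice's label, previous
slice's image, next slice's image). Each of the three inputs runs through
its own column of conv -> batch-norm -> ReLU blocks with per-level kernel
sizes; after every block the three columns are fused (channel concatenation
followed by a 1x1 convolution) and the fused maps, one per resolution, form
a feature pyramid that the segmentation encoder consumes at matching scales.
A deep-supervision head taps the deepest fused features and predicts a
full-resolution auxiliary mask whose cross entropy is added to the training
loss.

At stack boundaries a missing neighbour is "null": an all-zero plane of the
same size, which keeps every tensor shape independent of position in the
stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import ModelConfig
from .io_preproc import LabelStack, SliceStack

__all__ = ["ContextInput", "ContextFeatures", "make_context_input", "ContextNet"]


@dataclass
class ContextInput:
    """(prev_label, prev_image, next_image) for one slice; None means null."""

    prev_label: np.ndarray | None
    prev_image: np.ndarray | None
    next_image: np.ndarray | None

    def planes(self, size: int) -> np.ndarray:
        """Stack the three paths as a (3, size, size) array, zeros for null."""
        out = np.zeros((3, size, size), dtype=np.float64)
        for j, arr in enumerate((self.prev_label, self.prev_image, self.next_image)):
            if arr is not None:
                if arr.shape != (size, size):
                    raise ValueError(f"context plane {j} has shape {arr.shape}, "
                                     f"expected {(size, size)}")
                out[j] = arr
        return out


@dataclass
class ContextFeatures:
    """Fused per-resolution feature maps plus the deep-supervision logits."""

    pyramid: list          # nn.Tensor per level, halved resolution per level
    aux_logits: object | None = None


def make_context_input(stack: SliceStack, labels, i: int) -> ContextInput:
    """Build the context triple for slice ``i``.

    ``labels`` may be a LabelStack (teacher forcing) or any indexable list of
    masks (autoregressive predictions). The first slice has null previous
    label/image; the last slice has a null next image.
    """
    n = len(stack)
    if not 0 <= i < n:
        raise IndexError(f"slice index {i} out of range for {n}-slice stack")
    masks = getattr(labels, "masks", labels)
    prev_label = np.asarray(masks[i - 1]) if i > 0 else None
    prev_image = stack.slices[i - 1] if i > 0 else None
    next_image = stack.slices[i + 1] if i < n - 1 else None
    return ContextInput(prev_label, prev_image, next_image)


class _PathBlock(nn.Module):
    def __init__(self, c_in, c_out, k, rng):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, rng)
        self.bn = nn.BatchNorm2d(c_out)

    def __call__(self, x):
        return nn.relu(self.bn(self.conv(x)))


class ContextNet(nn.Module):
    """Three-column context extractor with cross-column fusion per level."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        config.validate()
        self.config = config
        ch, ks = config.channels, config.kernels
        self.paths = []
        for _ in range(3):
            blocks, c_in = [], 1
            for d in range(config.depth):
                blocks.append(_PathBlock(c_in, ch[d], ks[d], rng))
                c_in = ch[d]
            self.paths.append(blocks)
        # fusion: concat the three columns then mix with a 1x1 conv
        self.fusions = [nn.Conv2d(3 * ch[d], ch[d], 1, rng)
                        for d in range(config.depth)]
        self.aux_head = nn.Conv2d(ch[-1], 1, 1, rng)

    def _children(self):
        for blocks in self.paths:
            yield from blocks
        yield from self.fusions
        yield self.aux_head

    def named_parameters(self, prefix=""):
        for pi, blocks in enumerate(self.paths):
            for bi, blk in enumerate(blocks):
                yield from blk.named_parameters(f"{prefix}paths.{pi}.{bi}.")
        for fi, fusion in enumerate(self.fusions):
            yield from fusion.named_parameters(f"{prefix}fusions.{fi}.")
        yield from self.aux_head.named_parameters(f"{prefix}aux_head.")

    def named_buffers(self, prefix=""):
        for pi, blocks in enumerate(self.paths):
            for bi, blk in enumerate(blocks):
                yield from blk.named_buffers(f"{prefix}paths.{pi}.{bi}.")

    def __call__(self, ctx_planes: nn.Tensor, deep_supervision: bool = True):
        """ctx_planes: Tensor (N, 3, H, W) -> ContextFeatures.

        Fusion happens before pooling, so pyramid level d has resolution
        image_size / 2**d.
        """
        feats = [nn.Tensor(ctx_planes.data[:, j:j + 1], parents=(ctx_planes,),
                           backward=None)
                 for j in range(3)]
        pyramid = []
        for d in range(self.config.depth):
            feats = [self.paths[p][d](feats[p]) for p in range(3)]
            fused = self.fusions[d](nn.concat(feats))
            pyramid.append(fused)
            if d < self.config.depth - 1:
                feats = [nn.maxpool2d(f) for f in feats]
        aux = None
        if deep_supervision:
            factor = 2 ** (self.config.depth - 1)
            aux = nn.upsample_nearest(self.aux_head(pyramid[-1]), factor)
        return ContextFeatures(pyramid=pyramid, aux_logits=aux)
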