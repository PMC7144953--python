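"""NIfTI I/O, geometric preprocessing and cross-validation splits.

Short-axis cardiac MR arrives as a 3D volume: an ordered stack of 2D slices
with in-plane pixel spacing recorded in the header. The propagation
segmenter works on a fixed geometry — slices resampled to 1x1 mm and
center-cropped/padded to 128x128 — so this module provides the stack
containers, header-faithful readers/writers, the resample->crop pipeline and
reproducible k-fold splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from sklearn.model_selection import KFold

__all__ = [
    "SliceStack", "LabelStack", "FoldSplit", "read_volume", "write_volume",
    "read_labels", "write_labels", "resample_inplane", "crop_or_pad",
    "normalize_intensity", "split_kfold",
]


@dataclass
class SliceStack:
    """Ordered stack of 2D grayscale slices; index 0 is the top slice."""

    slices: list
    spacing: tuple  # in-plane (row, col) pixel size, mm
    id: str = ""

    def __post_init__(self):
        self.slices = [np.asarray(s) for s in self.slices]
        if not self.slices:
            raise ValueError("a SliceStack needs at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1 or self.slices[0].ndim != 2:
            raise ValueError(f"slices must share one 2D shape, got {shapes}")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    def __len__(self):
        return len(self.slices)

    @property
    def shape(self):
        return self.slices[0].shape

    def to_array(self) -> np.ndarray:
        return np.stack(self.slices, axis=0)


@dataclass
class LabelStack:
    """Binary masks (0=background, 1=myocardium) aligned with a SliceStack."""

    masks: list
    id: str = ""

    def __post_init__(self):
        self.masks = [np.asarray(m) for m in self.masks]
        if not self.masks:
            raise ValueError("a LabelStack needs at least one mask")
        for m in self.masks:
            if not np.isin(m, (0, 1)).all():
                raise ValueError("label values must be exactly 0 or 1")
        self.masks = [m.astype(np.uint8) for m in self.masks]

    def __len__(self):
        return len(self.masks)

    def to_array(self) -> np.ndarray:
        return np.stack(self.masks, axis=0)


@dataclass
class FoldSplit:
    fold_index: int
    train_ids: list
    test_ids: list
    validation_ids: list = field(default_factory=list)


def _spacing_from_header(img, axis):
    zooms = img.header.get_zooms()[:3]
    inplane = [z for i, z in enumerate(zooms) if i != axis]
    return (float(inplane[0]), float(inplane[1]))


def read_volume(path, axis: int = 2) -> SliceStack:
    """Read a 3D NIfTI volume as a SliceStack; `axis` is the through-plane axis."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D data in {path}")
    data = np.moveaxis(data, axis, 0)
    return SliceStack(slices=list(data), spacing=_spacing_from_header(img, axis),
                      id=str(path))


def write_volume(stack: SliceStack, path, slice_thickness: float = 1.0):
    """Write a SliceStack as NIfTI with spacing recorded in the header."""
    data = np.moveaxis(stack.to_array(), 0, 2)
    affine = np.diag([stack.spacing[0], stack.spacing[1], slice_thickness, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_labels(path, axis: int = 2) -> LabelStack:
    stack = read_volume(path, axis=axis)
    return LabelStack(masks=[np.rint(s).astype(np.uint8) for s in stack.slices],
                      id=str(path))


def write_labels(labels: LabelStack, spacing, path, slice_thickness: float = 1.0):
    stack = SliceStack(slices=[m.astype(np.int16) for m in labels.masks],
                       spacing=spacing, id=labels.id)
    write_volume(stack, path, slice_thickness)


def resample_inplane(stack: SliceStack, target_spacing,
                     labels: LabelStack | None = None):
    """Resample every slice to `target_spacing` (mm), preserving physical extent.

    Images are interpolated linearly; when `labels` is given its masks get the
    identical geometric transform with nearest-neighbour interpolation so
    values stay binary. Output size per axis is round(n * spacing / target).
    """
    ts = (float(target_spacing[0]), float(target_spacing[1]))
    if ts[0] <= 0 or ts[1] <= 0:
        raise ValueError(f"target spacing must be positive, got {ts}")
    zoom = (stack.spacing[0] / ts[0], stack.spacing[1] / ts[1])
    if zoom == (1.0, 1.0):
        out = SliceStack([s.copy() for s in stack.slices], ts, stack.id)
        out_labels = LabelStack([m.copy() for m in labels.masks], labels.id) if labels else None
        return (out, out_labels) if labels is not None else out

    def _zoom(arr, order):
        return ndimage.zoom(arr.astype(np.float64), zoom, order=order,
                            mode="grid-constant", grid_mode=True)

    out = SliceStack([_zoom(s, 1) for s in stack.slices], ts, stack.id)
    if labels is None:
        return out
    masks = [np.rint(_zoom(m, 0)).astype(np.uint8) for m in labels.masks]
    return out, LabelStack(masks, labels.id)


def _center_window(n_in: int, n_out: int):
    """Start indices for centered crop (src) or pad (dst)."""
    if n_in >= n_out:
        lo = (n_in - n_out) // 2
        return slice(lo, lo + n_out), slice(0, n_out)
    lo = (n_out - n_in) // 2
    return slice(0, n_in), slice(lo, lo + n_in)


def crop_or_pad(stack: SliceStack, size: int, labels: LabelStack | None = None):
    """Center-crop or zero-pad every slice to `size` x `size`.

    The identical window is applied to `labels` when given, keeping per-pixel
    alignment between image and mask.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    h, w = stack.shape
    rs, rd = _center_window(h, size)
    cs, cd = _center_window(w, size)

    def _apply(arr):
        out = np.zeros((size, size), dtype=arr.dtype)
        out[rd, cd] = arr[rs, cs]
        return out

    out = SliceStack([_apply(s) for s in stack.slices], stack.spacing, stack.id)
    if labels is None:
        return out
    return out, LabelStack([_apply(m) for m in labels.masks], labels.id)


def normalize_intensity(stack: SliceStack) -> SliceStack:
    """Per-volume z-score; a constant volume maps to all zeros."""
    vol = stack.to_array().astype(np.float64)
    sd = vol.std()
    if sd == 0:
        out = np.zeros_like(vol)
    else:
        out = (vol - vol.mean()) / sd
    return SliceStack(list(out), stack.spacing, stack.id)


def split_kfold(ids, k: int, seed: int, val_fraction: float = 0.25):
    """Reproducible k-fold splits with a validation set carved from non-test ids.

    Each id lands in exactly one test set across folds; within a fold the
    remaining ids are split into validation (`val_fraction` of them, rounded)
    and training. Defaults give the 3:1:1 train/test/validation proportion
    at k=5.
    """
    ids = list(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds dataset size {len(ids)}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    splits = []
    for fold, (rest_idx, test_idx) in enumerate(kf.split(ids)):
        rest = [ids[i] for i in rest_idx]
        rng = np.random.default_rng(np.random.SeedSequence([seed, fold]))
        perm = rng.permutation(len(rest))
        n_val = int(round(val_fraction * len(rest)))
        val_ids = [rest[i] for i in sorted(perm[:n_val])]
        train_ids = [rest[i] for i in sorted(perm[n_val:])]
        splits.append(FoldSplit(fold, train_ids, [ids[i] for i in test_idx], val_ids))
    return splits
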