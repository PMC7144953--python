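"""Synthetic annular-myocardium phantoms.

On short-axis cardiac MR the left-ventricular myocardium appears as a ring
of mid-range intensity around the bright blood pool, on a darker noisy
background — and it is not the only such structure in the field of view:
the right-ventricular wall, chest-wall muscle and the aorta produce
ring- or arc-like regions of essentially the same tissue intensity. Telling
*which* annulus is the myocardium is resolved anatomically by continuity
through the stack, which is precisely the information an autoregressive
slice-propagation segmenter exploits.

The generator emulates both aspects. Each slice's label is the annulus
between two concentric ellipses whose center performs a bounded random walk
(per-slice displacement <= ``center_drift``) and whose semi-axes a bounded
walk of step <= ``radius_drift``. ``n_distractors`` additional annuli of
identical tissue intensity (with their own bright lumina) drift
independently through the volume and are *not* part of the label. As in a
real stack, where neighbouring structures enter the field of view as the
imaging plane moves through the chest, the distractors are absent from the
top slice and appear (growing over two slices) a slice or two down. The top
slice is therefore unambiguous, while on deeper slices nothing in a single
image distinguishes the labelled ring from a look-alike — the reader, and
the model, must track it from the slice before.

Intensities default to an 8-bit-like MR appearance (background 50, muscle
110, blood pool 200, additive Gaussian noise sd 25); sizes default to the
128x128 working geometry. ``desk_params`` gives a half-size (64x64)
configuration for fast CPU training experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_preproc import LabelStack, SliceStack

__all__ = ["PhantomParams", "desk_params", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    n_slices: int = 8
    image_size: int = 128
    outer_radius: tuple = (18.0, 28.0)   # semi-axis range, px
    inner_radius: tuple = (10.0, 18.0)
    center_drift: float = 2.0            # max per-slice centroid displacement, px
    radius_drift: float = 1.0            # max per-slice semi-axis change, px
    n_distractors: int = 1               # unlabelled look-alike annuli
    intensity_bg: float = 50.0
    intensity_myo: float = 110.0
    intensity_blood: float = 200.0
    noise_sd: float = 25.0
    seed: int = 0

    def validate(self):
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if not (0 < self.inner_radius[0] <= self.inner_radius[1]):
            raise ValueError("inner_radius range must be positive and ordered")
        if not (0 < self.outer_radius[0] <= self.outer_radius[1]):
            raise ValueError("outer_radius range must be positive and ordered")
        if self.center_drift < 0 or self.radius_drift < 0 or self.noise_sd < 0:
            raise ValueError("drifts and noise_sd must be >= 0")
        if self.n_distractors < 0:
            raise ValueError("n_distractors must be >= 0")
        if self.outer_radius[1] * 2 >= self.image_size:
            raise ValueError("outer radius too large for image size")


def desk_params(**overrides) -> PhantomParams:
    """Half-size phantoms for fast CPU training runs."""
    base = PhantomParams(
        n_slices=6, image_size=64, outer_radius=(9.0, 14.0),
        inner_radius=(5.0, 9.0), center_drift=1.5, radius_drift=0.75)
    return replace(base, **overrides)


# annulus must stay at least this wide (px) so masks remain topological rings
_MIN_GAP = 2.0


def _rasterize(size, center, outer_ax, inner_ax):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    inside_outer = (dy / outer_ax[0]) ** 2 + (dx / outer_ax[1]) ** 2 <= 1.0
    inside_inner = (dy / inner_ax[0]) ** 2 + (dx / inner_ax[1]) ** 2 <= 1.0
    return inside_outer & ~inside_inner, inside_inner


class _Ring:
    """One drifting two-ellipse ring (continuous geometry + walk)."""

    def __init__(self, params: PhantomParams, rng, center):
        self.p = params
        ro_lo, ro_hi = params.outer_radius
        ri_lo, ri_hi = params.inner_radius
        self.center = np.asarray(center, dtype=np.float64)
        self.outer = rng.uniform(ro_lo, ro_hi, size=2)
        hi = max(ri_lo, min(ri_hi, self.outer.min() - _MIN_GAP))
        self.inner = rng.uniform(ri_lo, hi, size=2)

    def geometry(self):
        inner = np.minimum(self.inner, self.outer - _MIN_GAP)
        return self.center, self.outer, inner

    def step(self, rng, lo, hi):
        p = self.p
        theta = rng.uniform(0, 2 * np.pi)
        mag = rng.uniform(0, p.center_drift)
        self.center = np.clip(
            self.center + mag * np.array([np.sin(theta), np.cos(theta)]), lo, hi)
        self.outer = np.clip(
            self.outer + rng.uniform(-p.radius_drift, p.radius_drift, 2),
            *p.outer_radius)
        self.inner = np.clip(
            self.inner + rng.uniform(-p.radius_drift, p.radius_drift, 2),
            *p.inner_radius)


def generate_phantom(params: PhantomParams, stack_id: str = "phantom"):
    """Generate one (SliceStack, LabelStack) pair; deterministic in params.seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    margin = params.outer_radius[1] + 2.0
    lo, hi = margin, size - margin

    # target and distractors share one spatial distribution so that, once a
    # distractor is in view, no single-slice cue identifies the labelled ring
    target = _Ring(params, rng, rng.uniform(lo, hi, size=2))
    sep = 2.0 * params.outer_radius[1] + 2.0
    distractors = []
    for _ in range(params.n_distractors):
        cand = rng.uniform(lo, hi, size=2)
        for _attempt in range(200):
            if np.linalg.norm(cand - target.center) >= sep:
                break
            cand = rng.uniform(lo, hi, size=2)
        # absent from the top slice; enters the field of view a slice or
        # two down and grows to full size over two slices
        appear = int(rng.integers(1, 3))
        distractors.append((_Ring(params, rng, cand), appear))

    slices, masks = [], []
    for i in range(params.n_slices):
        img = np.full((size, size), params.intensity_bg, dtype=np.float64)
        for ring, appear in distractors:
            if i < appear:
                continue
            center, outer, inner = ring.geometry()
            scale = min(1.0, 0.5 * (i - appear + 1))
            annulus_d, blood_d = _rasterize(size, center, outer * scale,
                                            np.maximum(inner * scale, 0.5))
            img[blood_d] = params.intensity_blood
            img[annulus_d] = params.intensity_myo
        annulus, blood = _rasterize(size, *target.geometry())
        img[blood] = params.intensity_blood
        img[annulus] = params.intensity_myo
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, img.shape)
        slices.append(img)
        masks.append(annulus.astype(np.uint8))

        target.step(rng, lo, hi)
        for ring, _appear in distractors:
            ring.step(rng, lo, hi)
            # keep look-alikes from merging into the labelled ring
            delta = ring.center - target.center
            dist = np.linalg.norm(delta)
            if dist < sep:
                ring.center = target.center + delta / max(dist, 1e-9) * sep
                ring.center = np.clip(ring.center, lo, hi)

    return (SliceStack(slices, spacing=(1.0, 1.0), id=stack_id),
            LabelStack(masks, id=stack_id))


def generate_dataset(n_stacks: int, params: PhantomParams, seed: int):
    """Generate `n_stacks` independent phantoms, reproducible from (params, seed)."""
    if n_stacks < 1:
        raise ValueError("n_stacks must be >= 1")
    out = []
    for i in range(n_stacks):
        sub = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31))
        p = replace(params, seed=sub)
        out.append(generate_phantom(p, stack_id=f"phantom{i:03d}"))
    return out
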