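"""Teacher-forced training examples and autoregressive stack inference.

Training conditions every slice on the *ground-truth* label of its
predecessor (teacher forcing). At inference no ground truth exists, so the
stack is segmented in order — top slice first — and each slice's context
carries the *binarized prediction* of the slice just segmented. The first
slice has a null previous label/image and the last a null next image, so a
single-slice stack runs with an all-null context.

Because slice i's prediction reads only slices i-1, i, i+1 and the previous
prediction (itself a function of earlier slices), the prediction at slice i
is a deterministic function of slices 0..i+1 only.
"""

from __future__ import annotations

from .context_net import ContextInput, make_context_input
from .io_preproc import LabelStack, SliceStack
from .model import PropSegModel

__all__ = ["make_training_examples", "predict_stack"]


def _oriented(stack: SliceStack, labels, direction: str):
    if direction == "down":
        return stack, labels
    rev = SliceStack(list(reversed(stack.slices)), stack.spacing, stack.id)
    if labels is None:
        return rev, None
    masks = getattr(labels, "masks", labels)
    return rev, LabelStack(list(reversed(masks)), getattr(labels, "id", ""))


def make_training_examples(stack: SliceStack, labels: LabelStack,
                           direction: str = "down"):
    """One (slice, ContextInput, target) triple per slice, teacher-forced."""
    if len(stack) != len(labels):
        raise ValueError(f"stack has {len(stack)} slices but labels has "
                         f"{len(labels)} masks")
    stack, labels = _oriented(stack, labels, direction)
    return [(stack.slices[i], make_context_input(stack, labels, i),
             labels.masks[i]) for i in range(len(stack))]


def predict_stack(stack: SliceStack, model: PropSegModel, return_probs: bool = False):
    """Segment a stack autoregressively in the model's propagation direction.

    Slice 0 (in propagation order) runs with a null previous label; every
    later slice is conditioned on the binarized prediction of its
    predecessor. Returns a LabelStack aligned with the input order; with
    ``return_probs`` also the per-slice probability maps.
    """
    direction = model.config.direction
    work, _ = _oriented(stack, None, direction)
    masks, probs = [], []
    for i in range(len(work)):
        ctx = make_context_input(work, masks, i)
        prob = model.predict_proba(work.slices[i], ctx)
        probs.append(prob)
        masks.append((prob > model.config.threshold).astype("uint8"))
    if direction == "up":
        masks, probs = masks[::-1], probs[::-1]
    labels = LabelStack(masks, id=stack.id)
    return (labels, probs) if return_probs else labels
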