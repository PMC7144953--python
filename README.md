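# propseg

Autoregressive slice-propagation segmentation of the myocardium in
short-axis cardiac MR stacks.

## The problem

A short-axis cine-CMR acquisition is a stack of 2D slices through the
heart. On each slice the left-ventricular myocardium appears as a ring of
mid-range intensity around the bright blood pool — but it is not the only
ring-like structure in view: the right-ventricular wall, chest-wall muscle
and the aorta produce regions of essentially the same tissue intensity.
Purely 2D segmenters throw away the strongest cue a radiologist uses: the
myocardium on one slice is almost exactly where it was on the slice above.
Fully 3D convolutional models capture that cue but need far more data and
memory.

`propseg` implements a middle path: a 2D encoder-decoder segmenter whose
input for slice *i* is augmented by a **context module** reading the triple

```
( Label[i-1],  Ori[i-1],  Ori[i+1] )
```

— the previous slice's label and the neighbouring slices' images, each
through its own convolutional column (kernel sizes 7, 5, 3, … per level),
with the three columns fused at every resolution and a deep-supervision
head on the deepest fused features. At a stack boundary a missing neighbour
is an all-zero "null" plane. The segmentation net is U-Net-like: each
encoder level re-injects an average-pooled copy of the first level's
features, the decoder upsamples by transposed convolutions with skip
fusion, and a sigmoid head emits a per-pixel foreground probability.

Training uses **teacher forcing**: `Label[i-1]` is the ground-truth mask of
the slice above, and the loss is pixelwise binary cross entropy

&nbsp;&nbsp;&nbsp;&nbsp;L = −(1/m) Σᵢ [ yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ) ]

plus 0.4× the same loss on the deep-supervision head. Inference is
**autoregressive**: slices are segmented from the top slice to the bottom
one, and each slice's context carries the *binarized prediction* of its
predecessor, so every prediction conditions the next.

Evaluation uses the four standard overlap/ranking metrics: Dice
(DSC = 2|P∩G| / (|P|+|G|)), the rank-based (Mann–Whitney) AUC
((S₀ − n₀(n₀+1)/2) / n₀n₁ from the rank sum S₀ of foreground pixels), the
F1 score, and Jaccard (JSC = |P∩G| / |P∪G| = DSC/(2−DSC)).

Because no clinical data ships with the package, a phantom generator
produces stacks with the same structure: a drifting elliptical annulus of
muscle intensity around a bright lumen, plus look-alike rings that enter
the field of view partway down the stack — so single-slice appearance is
ambiguous and sequence continuity is the disambiguating signal, which is
exactly what the propagation model exploits. All networks and their
training run on plain numpy via a small built-in reverse-mode autodiff
engine; everything is seeded and bitwise reproducible.

## Worked example

```bash
python examples/train_and_propagate.py
```

trains a desk-scale model (64×64 phantoms, 12 training stacks; roughly two
minutes on one CPU) and prints:

```
validation DSC per epoch: [0.171, 0.283, 0.304, 0.224, 0.076, 0.056, 0.0,
                           0.28, 0.668, 0.771, 0.785, 0.862, 0.804, 0.84]
held-out stacks: 6
DSC 0.8290 +- 0.0224   AUC 0.9902   F1 0.8290   JSC 0.7137
mean DSC by slice position: [0.875 0.89  0.864 0.873 0.829 0.771 0.806 0.724]
```

The model reaches a held-out Dice of 0.83 on unseen stacks. Per-slice DSC
is highest near the top of the stack (where the context still carries
near-perfect labels) and declines gently with depth as the model's own
predictions replace ground truth and look-alike rings are in view; a model
without the context module collapses to ~0.5–0.6 DSC on these stacks
because nothing identifies which ring is the target.

Other examples: `examples/simulate_phantoms.py` (the generator and its
slice-to-slice coherence) and `examples/compute_metrics.py` (the metric
formulas on a hand-made case).

A thin CLI mirrors the library:

```bash
propseg simulate --n 10 --seed 0 --out data/        # phantom NIfTI pairs
propseg train --config cfg.yaml                     # weights + JSONL log
propseg cv --config cfg.yaml --k 5 --seed 0         # k-fold cross-validation
propseg predict --model run/model.npz --in vol.nii.gz --out lab.nii.gz
propseg evaluate --pred preds/ --truth labels/ --out report.json
```

## Layout

- `src/propseg/io_preproc.py` — NIfTI I/O, resampling to 1×1 mm, centered
  crop/pad to 128×128, per-volume z-scoring, k-fold splits
- `src/propseg/phantom.py` — the annulus phantom generator
- `src/propseg/context_net.py`, `seg_net.py`, `model.py` — the networks
- `src/propseg/propagation.py` — teacher forcing and autoregressive inference
- `src/propseg/metrics.py` — loss and the four evaluation metrics
- `src/propseg/trainer.py` — training loop, lr schedule, cross-validation
- `src/propseg/nn.py` — the numpy autodiff engine and layers
- `docs/methods.md` — model assumptions, parameter choices, limitations
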