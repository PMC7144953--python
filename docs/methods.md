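# Methods

## Model

`propseg` segments a 3D short-axis cardiac MR stack as an ordered sequence
of 2D problems. For slice *i* the model receives the slice itself plus a
context triple — the previous slice's label, the previous slice's image and
the next slice's image — and produces a per-pixel foreground probability.
Two sub-networks share the work:

**Context module.** Each of the three context inputs runs through its own
column of conv → batch-norm → ReLU blocks, one block per resolution level,
with decreasing kernel sizes (defaults 7, 5, 3, … per level) so the columns
see different fields of view. After every block the three columns are fused
by channel concatenation followed by a 1×1 convolution; the fused maps, one
per resolution, form a feature pyramid. A deep-supervision head (1×1
convolution plus nearest-neighbour upsampling) taps the deepest fused
features; its binary cross entropy enters the training loss with weight
`aux_weight` (default 0.4). The tap point and the weight are our choices —
deep supervision only pins down that an auxiliary loss exists, not where it
attaches or how strongly it counts.

**Segmentation module.** A U-Net-style encoder-decoder. Encoder level *d*
consumes the pooled features of level *d−1*, an average-pooled copy of the
*first* level's features (re-injection of raw-image detail, countering the
loss of fine structure with depth), and — when the context pathway is
enabled — the context pyramid level at the matching scale. The decoder has
one upsampling block per level: a stride-2 transposed convolution, skip
fusion with the corresponding encoder level, then two conv → BN → ReLU
layers. A description of the decoder as containing a pooling layer per
upsampling block would undo the upsampling it is meant to perform, so the
decoder here contains no pooling; this reading is deliberate and flagged.
The head is a single-channel 1×1 convolution with a sigmoid: for a
two-class problem a one-channel sigmoid and a two-channel softmax are
equivalent parameterizations, and the sigmoid keeps the loss simple.

**Null context.** At stack boundaries a missing neighbour is encoded as an
all-zero plane. Zeros are the least informative constant, keep every tensor
shape independent of slice position, and make the single-slice stack (all
three planes null) a well-defined degenerate case.

**Ablation twin.** The context-disabled variant is built with the identical
weight layout and seed; it simply routes all-zero context features. Its
output is therefore exactly independent of the context input, and the
on/off comparison is a pure pathway ablation, not an architecture change.

## Training and inference

Training uses teacher forcing: one example per slice, with the ground-truth
previous label in the context. The loss is mean pixelwise binary cross
entropy (computed stably from logits) plus the weighted deep-supervision
term. One widely printed form of this loss swaps *p* and *y* inside the
second logarithm, which is degenerate for binary targets (log of 0 whenever
y = 1); we use the standard form −[y log p + (1−y) log(1−p)].

Optimization is Adam (β = 0.9/0.999) at initial learning rate 0.001 with a
multiplicative decay of 0.9 every 10 iterations, lr(t) = 0.001·0.9^⌊t/10⌋.
Read literally per optimizer step, that schedule reaches numerically zero
within a few hundred steps — any run longer than a handful of epochs trains
only at its start — so the decay unit is configurable: the default profile
applies it per step (the literal reading), the desk-scale profile per
epoch. Batch size defaults to 5. After every epoch the model segments the
validation stacks autoregressively and the weights with the best validation
Dice are kept; pixel accuracy is logged alongside but not used for
selection, since plain accuracy is dominated by background pixels at ~6%
foreground fraction.

Inference is autoregressive in the configured direction (default: top slice
first): slice 0 runs with null context, and each later slice's context
carries the *binarized* prediction of its predecessor — binarized because
that is the data type the model saw in training ({0,1} masks), and no other
substitute for the unavailable ground truth is self-consistent. The
prediction at slice *i* is consequently an exact function of slices
0..*i*+1 only, a property the tests verify bitwise.

Everything is driven by explicit seeds (weight initialization by the model
config, shuffling by the run parameters) and all numerics are
deterministic, so identical inputs give bitwise-identical logs, weights and
reports.

## Preprocessing

Volumes are read from NIfTI with in-plane spacing taken from the header
(through-plane axis configurable, default the third axis). The working
geometry is fixed: resample in-plane to 1×1 mm (linear for images, nearest
neighbour for masks so they stay binary; `scipy.ndimage.zoom` with
`grid_mode=True`, i.e. pixel-area alignment, which preserves physical
extent = pixels × spacing), then center-crop or zero-pad to 128×128, in
that order. Intensities are z-scored per volume (a constant volume maps to
zeros). K-fold splits are seeded and carve a validation set from the
non-test ids (default fraction 0.25, giving 3:1:1 train/test/validation at
k = 5).

## The phantom generator

The phantom emulates the structure that makes stack propagation the right
tool, at the level of geometry and intensity statistics rather than MR
physics:

- the label is the annulus between two concentric ellipses (mild
  eccentricity avoids rotational degeneracy); muscle at gray level 110,
  lumen 200, background 50, additive Gaussian noise sd 25 — an 8-bit-like
  appearance with moderate tissue contrast;
- the ring's center performs a bounded random walk (per-slice displacement
  ≤ `center_drift`, default 2 px at 128²) and its semi-axes a bounded walk
  (≤ `radius_drift`, default 1 px), so adjacent ground-truth masks overlap
  strongly (mean DSC ≈ 0.90) and the overlap decays with slice distance —
  the previous label is an informative, decaying prior;
- `n_distractors` look-alike annuli (default 1) with identical intensities
  drift independently. They are absent from the top slice and enter the
  field of view one or two slices down, growing over two slices, as
  neighbouring anatomy does when the imaging plane moves through the chest.
  Target and distractors share one spatial distribution, so once a
  distractor is in view nothing in a single image identifies the labelled
  ring; a minimum separation keeps the rings from merging.

The distractors are the load-bearing design choice. Development experiments
showed that with a lone ring in noise a single-slice segmenter equals or
beats the context-conditioned model at every noise and contrast level
tried: the image alone suffices, the previous label adds nothing, and the
autoregressive chain only adds exposure-bias variance (teacher-forced
accuracy was high and flat across slices; autoregressive accuracy decayed
down the stack). Identification ambiguity — not pixel noise — is what makes
the task genuinely sequential, and it is also the honest analogue of the
clinical task, where the reader disambiguates look-alike structures by
scrolling. With distractors present the context-conditioned model scores
mean Dice ≈ 0.80–0.93 (depending on scale) against ≈ 0.50–0.70 for its
context-disabled twin.

What the phantom does *not* model: bias fields, coil profiles, motion and
flow artifacts, through-plane intensity variation, partial-volume effects,
anatomical shape variability, and multi-structure labels. Passing tests on
phantoms therefore demonstrate the propagation mechanism, the training
recipe and the exact metric arithmetic — not clinical-grade accuracy.

## Numerical choices

- The networks run on a small reverse-mode autodiff engine over numpy
  (im2col convolutions, non-overlapping transposed convolutions, 2×2 max
  pooling with tie-split gradients, batch norm with running statistics).
  Gradients are verified against central differences to ~1e-9 relative
  error in float64; training uses float32.
- Binarization threshold 0.5, strict inequality (a pixel at exactly the
  threshold is background).
- Cross entropy clips probabilities to [1e-7, 1 − 1e-7]; the training loss
  is computed from logits and needs no clipping.
- Dice as a bit-vector formula uses squared L2 norms, which reduces to
  2|P∩G|/(|P|+|G|); unsquared norms would not reduce to Dice and are
  rejected as a misprint.
- Rank AUC uses 1-based midranks for ties, making it the
  ties-count-half pairwise ordering probability (Mann–Whitney form); it is
  undefined for single-class ground truth, and such slices are skipped in
  aggregation.
- Overlap metrics between two empty masks score 1.0 (the conventional
  choice, so a correctly-empty prediction is not penalized).
- Weight initialization: He fan-in scaling from the config seed.

## Desk-scale study conditions

CPU experiments use 64×64 phantoms with 8 slices, a depth-3 model with
(8, 16, 32) channels and kernels (7, 5, 3), batch size 5, per-epoch lr
decay. The end-to-end check trains on 36 stacks (plus 4 validation) for 15
epochs and evaluates 10 held-out stacks; the ablation check uses 12/2/6
stacks for 10 epochs across three seeds. These sizes were chosen as the
smallest at which training converges reliably; larger runs only improve
the margins.

## Known limitations

- Exposure bias is inherent to teacher forcing: accuracy decays modestly
  down the stack as the model consumes its own predictions. Scheduled
  sampling would mitigate it but is deliberately out of scope — training
  conditions on ground truth only.
- A wrong prediction early in the chain can propagate; there is no
  bidirectional or ensemble pass.
- The context pathway costs roughly half the parameter budget and slows
  convergence early in training; its benefit appears only when the task is
  sequentially ambiguous.
- Only single-foreground-class (binary) segmentation is implemented.
- 4D (cine time axis) data and DICOM ingestion are out of scope; each
  volume is treated as one stack of one phase.
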