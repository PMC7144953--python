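"""The four evaluation metrics on a small hand-made example.

DSC and F1 coincide for binary masks, Jaccard relates to DSC through
J = D / (2 - D), and the rank AUC is the probability that a random
foreground pixel is scored above a random background pixel.
"""

import numpy as np

from propseg import cross_entropy, dice, f1, jaccard, rank_auc

truth = np.zeros((8, 8), dtype=int)
truth[2:6, 2:6] = 1            # a 16-pixel square "myocardium"
pred = np.zeros((8, 8), dtype=int)
pred[3:7, 2:6] = 1             # shifted one row down: 12 pixels overlap

print(f"|truth| = {truth.sum()}, |pred| = {pred.sum()}, "
      f"|intersection| = {(pred * truth).sum()}")
print(f"DSC     = {dice(pred, truth):.4f}   (2*12 / (16+16))")
print(f"F1      = {f1(pred, truth):.4f}   (equals DSC for binary masks)")
print(f"Jaccard = {jaccard(pred, truth):.4f}   (= DSC / (2 - DSC))")

scores = np.where(pred == 1, 0.9, 0.1) + np.random.default_rng(0).normal(
    0, 0.01, truth.shape)
print(f"rank AUC of those scores vs truth = {rank_auc(scores, truth):.4f}")
print(f"cross entropy of a perfect probability map = "
      f"{cross_entropy(truth.astype(float), truth.astype(float)):.2e}")
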