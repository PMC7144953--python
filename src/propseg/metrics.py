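"""Loss and evaluation metrics for binary myocardium segmentation.

Implements pixelwise binary cross entropy, the Dice similarity coefficient
(DSC), the rank-based (Mann-Whitney) AUC, the F1 score and the Jaccard
similarity coefficient (JSC), plus stack- and fold-level aggregation into a
:class:`MetricsReport`.

Conventions: overlap metrics between two empty masks score 1.0; AUC uses
midranks for tied scores, making it the probability that a random foreground
pixel outranks a random background pixel with ties counted as 1/2; AUC is
undefined (raises) when the ground truth contains a single class, and such
slices are skipped during aggregation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "cross_entropy", "dice", "rank_auc", "f1", "jaccard", "evaluate",
    "MetricsReport", "UndefinedMetricError",
]

EPS = 1e-7


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. single-class AUC)."""


def _check_binary(*masks):
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    for m in masks:
        if not np.isin(m, (0, 1)).all():
            raise ValueError("masks must contain only 0 and 1")


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross entropy -[y log p + (1-y) log(1-p)] over all pixels.

    Probabilities are clipped to [EPS, 1-EPS] before taking logs.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|P∩G| / (|P|+|G|); 1.0 if both empty."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_binary(pred, truth)
    inter = float((pred * truth).sum())
    denom = float(pred.sum() + truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard similarity coefficient |P∩G| / |P∪G|; 1.0 if both empty."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_binary(pred, truth)
    inter = float((pred * truth).sum())
    union = float(pred.sum() + truth.sum()) - inter
    if union == 0:
        return 1.0
    return inter / union


def f1(pred: np.ndarray, truth: np.ndarray) -> float:
    """F1 score, the harmonic mean of precision and recall; 0 when both are 0.

    For binary masks this equals the Dice coefficient analytically.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_binary(pred, truth)
    tp = float((pred * truth).sum())
    p_sum, g_sum = float(pred.sum()), float(truth.sum())
    if p_sum == 0 and g_sum == 0:
        return 1.0
    if tp == 0:
        return 0.0
    precision = tp / p_sum
    recall = tp / g_sum
    return 2.0 * precision * recall / (precision + recall)


def rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-sum AUC: (S0 - n0(n0+1)/2) / (n0 n1).

    ``n0`` is the number of foreground (ground-truth-positive) pixels, ``n1``
    the rest, and S0 the sum of the (1-based, midrank-tied) ranks of the
    foreground pixels when all pixels are ranked by score ascending.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same size")
    pos = truth == 1
    n0 = int(pos.sum())
    n1 = truth.size - n0
    if n0 == 0 or n1 == 0:
        raise UndefinedMetricError("AUC undefined for single-class ground truth")
    ranks = rankdata(scores, method="average")
    s0 = float(ranks[pos].sum())
    return (s0 - n0 * (n0 + 1) / 2.0) / (n0 * n1)


@dataclass
class MetricsReport:
    """Per-stack and aggregate segmentation metrics.

    ``per_stack`` maps stack id -> {"dsc": .., "auc": .., "f1": .., "jsc": ..}
    (slice-averaged). ``aggregate`` holds mean and std over stacks. When
    reports from several folds are merged, ``folds`` keeps each fold's
    aggregate and ``aggregate`` becomes mean/std across fold means.
    """

    per_stack: dict = field(default_factory=dict)
    aggregate: dict = field(default_factory=dict)
    folds: list = field(default_factory=list)

    METRICS = ("dsc", "auc", "f1", "jsc")

    @staticmethod
    def _summarize(rows: list[dict]) -> dict:
        agg = {}
        for m in MetricsReport.METRICS:
            vals = [r[m] for r in rows if r.get(m) is not None and np.isfinite(r[m])]
            if vals:
                agg[f"{m}_mean"] = float(np.mean(vals))
                agg[f"{m}_std"] = float(np.std(vals))
            else:
                agg[f"{m}_mean"] = float("nan")
                agg[f"{m}_std"] = float("nan")
        return agg

    def finalize(self):
        self.aggregate = self._summarize(list(self.per_stack.values()))
        return self

    @classmethod
    def across_folds(cls, reports: list["MetricsReport"]) -> "MetricsReport":
        out = cls()
        for r in reports:
            out.per_stack.update(r.per_stack)
            out.folds.append(r.aggregate)
        rows = [{m: f[f"{m}_mean"] for m in cls.METRICS} for f in out.folds]
        out.aggregate = cls._summarize(rows)
        return out

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"per_stack": self.per_stack, "aggregate": self.aggregate,
                       "folds": self.folds}, fh, indent=2)

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["stack_id", *self.METRICS])
            for sid, row in self.per_stack.items():
                writer.writerow([sid, *[row[m] for m in self.METRICS]])


def evaluate(predictions, truths, prob_maps=None) -> MetricsReport:
    """Score predicted label stacks against ground truth.

    Parameters
    ----------
    predictions, truths : sequences of LabelStack (or of mask lists)
    prob_maps : optional matching sequence of per-slice probability maps used
        as AUC scores; when omitted the binary predictions themselves are
        ranked (coarser but still defined).
    """
    if len(predictions) == 0 or len(predictions) != len(truths):
        raise ValueError("predictions and truths must be nonempty and aligned")
    report = MetricsReport()
    for idx, (pred, truth) in enumerate(zip(predictions, truths)):
        pred_masks = getattr(pred, "masks", pred)
        true_masks = getattr(truth, "masks", truth)
        sid = getattr(pred, "id", None) or getattr(truth, "id", None) or f"stack{idx}"
        if len(pred_masks) != len(true_masks):
            raise ValueError(f"stack {sid}: slice counts differ")
        dscs, f1s, jscs, aucs = [], [], [], []
        for j, (pm, tm) in enumerate(zip(pred_masks, true_masks)):
            dscs.append(dice(pm, tm))
            f1s.append(f1(pm, tm))
            jscs.append(jaccard(pm, tm))
            scores = prob_maps[idx][j] if prob_maps is not None else pm
            try:
                aucs.append(rank_auc(scores, tm))
            except UndefinedMetricError:
                pass  # single-class slice: AUC skipped
        report.per_stack[sid] = {
            "dsc": float(np.mean(dscs)),
            "f1": float(np.mean(f1s)),
            "jsc": float(np.mean(jscs)),
            "auc": float(np.mean(aucs)) if aucs else None,
        }
    return report.finalize()
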