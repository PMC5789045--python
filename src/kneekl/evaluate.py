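"""Evaluation panel for KL grading: ordinal agreement, error and OA screening.

The panel mirrors how radiographic grading models are reported: a 5x5
confusion matrix, average multi-class accuracy (mean per-class recall; plain
accuracy is emitted alongside), Cohen's kappa with quadratic weights —
penalising a 0-vs-4 disagreement far more than a 1-vs-2 — the mean squared
error of the hard grade predictions, and the ROC/AUC of the binary
radiographic-OA decision (KL >= 2) scored by the tail probability mass.

Also hosts weight-free architecture shape probes: the Siamese branch trace and
a ResNet-34 layer-arithmetic walk, used to report attention-map resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ArchitectureError
from .model import BranchSpec, spatial_trace

__all__ = ["EvalReport", "quadratic_kappa", "grade_mse",
           "avg_multiclass_accuracy", "plain_accuracy", "oa_roc",
           "evaluate", "shape_probe"]

N_GRADES = 5


@dataclass
class EvalReport:
    """Full metric panel over one prediction set."""

    confusion: np.ndarray
    avg_accuracy: float
    plain_accuracy: float
    kappa_quadratic: float
    mse: float
    auc_oa: float
    n: int
    roc_points: tuple[np.ndarray, np.ndarray] | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "avg_accuracy": self.avg_accuracy,
            "plain_accuracy": self.plain_accuracy,
            "kappa_quadratic": self.kappa_quadratic,
            "mse": self.mse,
            "auc_oa": self.auc_oa,
            "n": self.n,
        }
        if self.roc_points is not None:
            d["roc_fpr"] = self.roc_points[0].tolist()
            d["roc_tpr"] = self.roc_points[1].tolist()
        return d


def _as_grades(values, name: str) -> np.ndarray:
    a = np.asarray(values)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if a.size and (a.min() < 0 or a.max() >= N_GRADES or not
                   np.issubdtype(a.dtype, np.integer)):
        a = a.astype(int)
        if (a < 0).any() or (a >= N_GRADES).any():
            raise ValueError(f"{name} must contain grades 0..4")
    return a.astype(int)


def quadratic_kappa(truth, pred) -> float:
    """Cohen's kappa with quadratic weights w_ij = 1 - (i-j)^2 / (K-1)^2.

    Expected agreement comes from the outer product of the two marginal
    distributions, the standard two-rater chance model.

    Raises
    ------
    ValueError
        If fewer than two samples are given, lengths differ, or both raters
        use one and the same single grade (kappa undefined: no chance
        disagreement to correct for).
    """
    t, p = _as_grades(truth, "truth"), _as_grades(pred, "pred")
    if t.shape != p.shape or t.size < 2:
        raise ValueError("truth and pred must have equal length >= 2")
    n = t.size
    conf = np.zeros((N_GRADES, N_GRADES))
    np.add.at(conf, (t, p), 1.0)
    i, j = np.meshgrid(np.arange(N_GRADES), np.arange(N_GRADES), indexing="ij")
    w = 1.0 - (i - j) ** 2 / (N_GRADES - 1) ** 2
    po = float((w * conf).sum() / n)
    expected = np.outer(conf.sum(axis=1), conf.sum(axis=0)) / n**2
    pe = float((w * expected).sum())
    if abs(1.0 - pe) < 1e-12:
        raise ValueError("kappa undefined: degenerate single-grade marginals")
    return (po - pe) / (1.0 - pe)


def grade_mse(truth, pred_dists) -> float:
    """Mean squared error between true grades and argmax predicted grades."""
    t = _as_grades(truth, "truth")
    probs = np.asarray([d.probs if hasattr(d, "probs") else d for d in pred_dists])
    if probs.shape[0] != t.size:
        raise ValueError("truth and predictions must have equal length")
    hard = probs.argmax(axis=1)
    return float(np.mean((hard - t) ** 2))


def avg_multiclass_accuracy(confusion: np.ndarray) -> float:
    """Mean per-class recall (balanced accuracy); empty truth rows are ignored."""
    conf = np.asarray(confusion, dtype=float)
    if conf.sum() <= 0:
        raise ValueError("empty confusion matrix")
    row_sums = conf.sum(axis=1)
    present = row_sums > 0
    return float((np.diag(conf)[present] / row_sums[present]).mean())


def plain_accuracy(confusion: np.ndarray) -> float:
    conf = np.asarray(confusion, dtype=float)
    return float(np.trace(conf) / conf.sum())


def oa_roc(truth, scores):
    """ROC curve and AUC of the binary radiographic-OA decision (KL >= 2).

    ``scores`` are the p(KL>=2) tail masses.  Returns ``((fpr, tpr), auc)``.
    """
    t = _as_grades(truth, "truth")
    s = np.asarray(scores, dtype=float)
    positive = (t >= 2).astype(int)
    if positive.min() == positive.max():
        raise ValueError("both OA and non-OA cases are required for a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(positive, s)
    return (fpr, tpr), float(_sk_auc(fpr, tpr))


def evaluate(truth, pred_dists) -> EvalReport:
    """Assemble the full panel from true grades and predicted distributions."""
    t = _as_grades(truth, "truth")
    probs = np.asarray([d.probs if hasattr(d, "probs") else d for d in pred_dists])
    hard = probs.argmax(axis=1)
    conf = _sk_confusion(t, hard, labels=range(N_GRADES))
    oa_scores = probs[:, 2:].sum(axis=1)
    try:
        (fpr, tpr), auc_val = oa_roc(t, oa_scores)
        roc_points = (fpr, tpr)
    except ValueError:
        auc_val, roc_points = float("nan"), None
    return EvalReport(
        confusion=conf,
        avg_accuracy=avg_multiclass_accuracy(conf),
        plain_accuracy=plain_accuracy(conf),
        kappa_quadratic=quadratic_kappa(t, hard),
        mse=float(np.mean((hard - t) ** 2)),
        auc_oa=auc_val,
        n=t.size,
        roc_points=roc_points,
    )


def _conv_out(n: int, kernel: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - kernel) // stride + 1


def shape_probe(arch: str, input_px: int) -> int:
    """Spatial side of the last pre-pooling activation map, weight-free.

    ``"siamese_branch"`` walks the default branch trace; ``"resnet34"`` walks
    the standard ResNet-34 layer list (7x7/2 stem with padding 3, 3x3/2
    max-pool with padding 1, then residual stages of [3, 4, 6, 3] basic blocks
    whose 3x3 convolutions keep the size except the stride-2 stage entries).
    """
    if input_px < 1:
        raise ValueError("input_px must be positive")
    if arch == "siamese_branch":
        return spatial_trace(BranchSpec.default(), input_px)[-1]
    if arch == "resnet34":
        n = _conv_out(input_px, 7, 2, 3)   # stem convolution
        n = _conv_out(n, 3, 2, 1)          # stem max-pool
        for blocks, stage_stride in ((3, 1), (4, 2), (6, 2), (3, 2)):
            for b in range(blocks):
                s = stage_stride if b == 0 else 1
                n = _conv_out(n, 3, s, 1)
                n = _conv_out(n, 3, 1, 1)
                if n < 1:
                    raise ArchitectureError(
                        f"input of {input_px} px collapses inside ResNet-34")
        return n
    raise ValueError("arch must be 'siamese_branch' or 'resnet34'")
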