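"""Vessel segmentation evaluation restricted to the field of view.

Out-of-FOV pixels are trivially background and inflate pixel-wise scores, so
every metric here counts FOV pixels only.  Dice coefficient (numerically the
F1 score for binary vessel segmentation) and the area under the
precision-recall curve are the preferred metrics because they respect the
heavy vessel/background class imbalance; accuracy, sensitivity and
specificity are provided as the conventional reporting set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve

__all__ = ["EvalResult", "dice", "aupr", "confusion_metrics", "evaluate"]


@dataclass
class EvalResult:
    dice: float
    aupr: float | None
    accuracy: float
    sensitivity: float
    specificity: float
    n_fov_pixels: int


def _flatten(pred, gt, fov):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt must share a shape")
    if fov is None:
        sel = np.ones(gt.shape, dtype=bool)
    else:
        sel = np.asarray(fov, dtype=bool)
        if sel.shape != gt.shape:
            raise ValueError("fov must share the mask shape")
    return pred[sel], gt[sel]


def dice(pred: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None) -> float:
    """Dice coefficient ``2|P∩G| / (|P| + |G|)`` over FOV pixels.

    Both masks empty inside the FOV is a perfect (vacuous) agreement: 1.
    """
    p, g = _flatten(np.asarray(pred, dtype=bool), np.asarray(gt, dtype=bool), fov)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def aupr(prob: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None) -> float:
    """Area under the precision-recall curve over FOV pixels.

    Integration is the step-wise sum ``Σ (R_n − R_{n−1}) · P_n`` over the
    exact curve (no trapezoidal interpolation, which is optimistically
    biased for PR curves).
    """
    p, g = _flatten(np.asarray(prob, dtype=float), np.asarray(gt, dtype=bool), fov)
    if not g.any():
        raise ValueError("ground truth has no vessel pixel inside the FOV")
    precision, recall, _ = precision_recall_curve(g.astype(int), p)
    # curve is returned with recall decreasing; step-integrate
    return float(-np.sum(np.diff(recall) * np.array(precision)[:-1]))


def confusion_metrics(
    pred: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from FOV-restricted 2x2 counts."""
    p, g = _flatten(np.asarray(pred, dtype=bool), np.asarray(gt, dtype=bool), fov)
    tp = int((p & g).sum())
    tn = int((~p & ~g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 1.0
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    return acc, sens, spec


def evaluate(
    pred: np.ndarray,
    gt: np.ndarray,
    fov: np.ndarray | None = None,
    prob: np.ndarray | None = None,
) -> EvalResult:
    """Full FOV-restricted evaluation; AUPR only when a probability map is
    supplied."""
    acc, sens, spec = confusion_metrics(pred, gt, fov)
    n = int(np.asarray(fov, dtype=bool).sum()) if fov is not None else int(
        np.asarray(gt).size
    )
    return EvalResult(
        dice=dice(pred, gt, fov),
        aupr=aupr(prob, gt, fov) if prob is not None else None,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        n_fov_pixels=n,
    )
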