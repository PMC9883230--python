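"""Detection metrics: confusion counts, SE/SP/P/AC, PR and ROC curves.

At a score threshold the four confusion counts give

    SE = TP / (TP + FN)      sensitivity (recall)
    SP = TN / (TN + FP)      specificity
    P  = TP / (TP + FP)      precision
    AC = (TP + TN) / (TP + TN + FP + FN)

PR and ROC curves sweep every distinct score threshold; areas under both
curves are computed by the trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm


@dataclass
class DetectionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    se: float
    sp: float
    p: float
    ac: float
    pr_curve: np.ndarray    # (n, 3): threshold, recall, precision
    roc_curve: np.ndarray   # (n, 3): threshold, fpr, tpr
    auc_pr: float
    auc_roc: float


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float, float]:
    """(SE, SP, P, AC) from raw confusion counts."""
    se = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    p = tp / (tp + fp) if tp + fp else float("nan")
    ac = (tp + tn) / (tp + tn + fp + fn)
    return se, sp, p, ac


def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> DetectionMetrics:
    """Full evaluation of scored predictions against binary labels.

    `scores` are p(hemorrhage); `labels` are {0, 1}.  Both classes must be
    present, otherwise SE or SP is undefined and an error names the missing
    class.  Curves come from scikit-learn's threshold sweeps; the summary
    counts and SE/SP/P/AC are computed directly from the definitions.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not (y == 1).any():
        raise ValueError("no positive labels: SE undefined")
    if not (y == 0).any():
        raise ValueError("no negative labels: SP undefined")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    se, sp, p, ac = confusion_metrics(tp, tn, fp, fn)

    precision, recall, pr_thresh = skm.precision_recall_curve(y, s)
    # curve points ordered by ascending threshold; the final (recall 0,
    # precision 1) endpoint has no threshold and is kept with threshold inf
    pr_t = np.concatenate([pr_thresh, [np.inf]])
    pr_curve = np.stack([pr_t, recall, precision], axis=1)
    # trapezoid over recall (recall is descending along the sweep)
    auc_pr = float(-np.trapezoid(precision, recall))

    fpr, tpr, roc_thresh = skm.roc_curve(y, s)
    roc_points = np.stack([roc_thresh, fpr, tpr], axis=1)
    roc_points = roc_points[np.argsort(roc_points[:, 0])]
    auc_roc = float(np.trapezoid(tpr, fpr))

    return DetectionMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn, se=se, sp=sp, p=p, ac=ac,
        pr_curve=pr_curve, roc_curve=roc_points,
        auc_pr=auc_pr, auc_roc=auc_roc,
    )
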