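"""Benchmark metrics: confusion counts at an FDR threshold and auROC.

Evaluation is restricted to the unchanged peaks plus one change class
at a time, so that power against profile changes and against affinity
changes is reported separately.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from peakshape.errors import InvalidInputError

__all__ = ["auroc", "ranking_scores", "evaluate_calls", "roc_points"]

_CLASS_LABEL = {
    "profile": "profile_change",
    "affinity": "affinity_change",
}


def auroc(scores, labels) -> float:
    """P(positive outranks negative), ties counted 1/2 (Mann-Whitney).

    ``labels`` are boolean (True = positive); higher score ranks first.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise InvalidInputError("scores and labels must be aligned")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("auROC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def ranking_scores(p_values, statistics=None) -> np.ndarray:
    """Total-order significance scores: ascending p, ties broken by
    descending raw statistic, then input order; higher = more significant.

    NaN p (skipped peaks) ranks last; NaN statistics rank after real ones.
    """
    p = np.asarray(p_values, dtype=np.float64)
    p = np.where(np.isnan(p), np.inf, p)
    if statistics is None:
        stat = np.zeros_like(p)
    else:
        stat = np.asarray(statistics, dtype=np.float64)
        stat = np.where(np.isnan(stat), -np.inf, stat)
    order = np.lexsort((np.arange(p.size), -stat, p))
    scores = np.empty(p.size, dtype=np.float64)
    scores[order] = -np.arange(p.size, dtype=np.float64)
    return scores


def evaluate_calls(
    q_values,
    threshold: float,
    truth,
    change_class: str,
    p_values=None,
    statistics=None,
) -> dict:
    """Confusion counts, eFDR/SN/SP (%) and auROC (%) for one change class.

    ``truth`` is a per-peak label vector (or an object with a ``labels``
    attribute) with values unchanged / affinity_change / profile_change;
    only unchanged peaks and the selected class enter the evaluation.
    Calls are ``q < threshold`` (NaN q = not called).  eFDR is NaN when
    nothing is called.  auROC ranks by p with ties broken by the raw
    statistic (q-values are used if no p-values are given).
    """
    labels = np.asarray(getattr(truth, "labels", truth))
    q = np.asarray(q_values, dtype=np.float64)
    if q.shape != labels.shape:
        raise InvalidInputError("q-values and truth labels must be aligned")
    if change_class not in _CLASS_LABEL:
        raise InvalidInputError(f"change_class must be one of {sorted(_CLASS_LABEL)}")
    positive_label = _CLASS_LABEL[change_class]

    keep = (labels == "unchanged") | (labels == positive_label)
    q = q[keep]
    is_pos = labels[keep] == positive_label
    called = np.where(np.isnan(q), False, q < threshold)

    tp = int((called & is_pos).sum())
    fp = int((called & ~is_pos).sum())
    fn = int((~called & is_pos).sum())
    tn = int((~called & ~is_pos).sum())
    efdr = np.nan if tp + fp == 0 else 100.0 * fp / (tp + fp)
    sn = np.nan if tp + fn == 0 else 100.0 * tp / (tp + fn)
    sp = np.nan if tn + fp == 0 else 100.0 * tn / (tn + fp)

    if p_values is None:
        p_values = q_values
    p = np.asarray(p_values, dtype=np.float64)[keep]
    stat = None if statistics is None else np.asarray(statistics, dtype=np.float64)[keep]
    roc = 100.0 * auroc(ranking_scores(p, stat), is_pos)

    return {
        "TP": tp, "FP": fp, "FN": fn, "TN": tn,
        "eFDR": efdr, "SN": sn, "SP": sp, "auROC": roc,
    }


def roc_points(scores, labels) -> np.ndarray:
    """(FPR, TPR) coordinates sweeping the score threshold, for plotting.

    Returns an (k, 2) array from (0, 0) to (1, 1); ties share a point.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("ROC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    last_of_tie = np.r_[s[1:] != s[:-1], True]
    tpr = tps[last_of_tie] / n_pos
    fpr = fps[last_of_tie] / n_neg
    return np.vstack([np.r_[0.0, fpr], np.r_[0.0, tpr]]).T
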