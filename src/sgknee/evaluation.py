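"""Metrics and cross-validation plumbing.

Conventions: an ACL tear is the positive class; sensitivity is the true
positive rate on tear exams, specificity the true negative rate on intact
exams.  AUC is computed by the midrank Mann-Whitney statistic, equal to
the probability a random positive outscores a random negative (ties count
half) — exact under ties, no threshold grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = ["MetricsReport", "FoldPlan", "confusion_metrics", "auc_score", "make_folds", "roc_points"]


@dataclass
class MetricsReport:
    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


@dataclass
class FoldPlan:
    """k stratified folds of exam ids, each with a nested train/tune split."""

    folds: list[dict]  # keys: train, tune, valid -> lists of exam ids
    k: int
    tune_frac: float


def confusion_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """Confusion counts plus accuracy / sensitivity / specificity (and AUC
    when continuous scores are supplied).

    Sensitivity requires at least one positive and specificity at least one
    negative in ``y_true``; otherwise the rate is undefined and an error is
    raised rather than silently reporting 0/0.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not set(np.unique(yt)) <= {0, 1} or not set(np.unique(yp)) <= {0, 1}:
        raise ValueError("labels and predictions must be binary 0/1")
    P = int(np.sum(yt == 1))
    N = int(np.sum(yt == 0))
    if P == 0:
        raise ValueError("no positive cases: sensitivity undefined")
    if N == 0:
        raise ValueError("no negative cases: specificity undefined")
    TP = int(np.sum((yt == 1) & (yp == 1)))
    FN = P - TP
    TN = int(np.sum((yt == 0) & (yp == 0)))
    FP = N - TN
    auc = auc_score(yt, scores) if scores is not None else None
    return MetricsReport(
        TP=TP,
        FP=FP,
        TN=TN,
        FN=FN,
        accuracy=(TP + TN) / (P + N),
        sensitivity=TP / P,
        specificity=TN / N,
        auc=auc,
    )


def auc_score(y_true, scores) -> float:
    """Midrank Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    yt = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # midranks under ties
    r_pos = np.sum(ranks[yt == 1])
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(y_true, scores) -> pd.DataFrame:
    """(FPR, TPR) pairs at every distinct score threshold, for ROC export."""
    yt = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    yt = yt[order]
    s = s[order]
    P = np.sum(yt == 1)
    N = np.sum(yt == 0)
    tps = np.cumsum(yt == 1)
    fps = np.cumsum(yt == 0)
    keep = np.r_[np.diff(s) != 0, True]  # last point of each tie block
    fpr = np.r_[0.0, fps[keep] / N]
    tpr = np.r_[0.0, tps[keep] / P]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def make_folds(manifest, k: int, tune_frac: float = 0.2, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan with a nested stratified train/tune split.

    Each fold's held-out portion is ``valid``; the remainder is split
    (1 - tune_frac) / tune_frac into ``train`` and ``tune``, preserving
    class proportions throughout.  Deterministic under ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = np.array(manifest.exam_ids)
    labels = manifest.labels
    for cls in (0, 1):
        if np.sum(labels == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for rest_idx, valid_idx in skf.split(ids, labels):
        train_idx, tune_idx = train_test_split(
            rest_idx,
            test_size=tune_frac,
            stratify=labels[rest_idx],
            random_state=seed,
        )
        folds.append(
            {
                "train": list(ids[np.sort(train_idx)]),
                "tune": list(ids[np.sort(tune_idx)]),
                "valid": list(ids[np.sort(valid_idx)]),
            }
        )
    return FoldPlan(folds=folds, k=k, tune_frac=tune_frac)
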