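"""Binary-classification metrics and the repeated stratified k-fold harness.

The four headline indices are precision, sensitivity, accuracy and the
Matthews correlation coefficient,

    Pre = TP / (TP + FP)
    Sen = TP / (TP + FN)
    Acc = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)),

with the interacting pair as the positive class.  Acc/Sen/Pre are reported as
percentages; MCC lies in [-1, 1].  A zero denominator yields NaN with a
warning, never a silent 0.  ROC/AUC uses a threshold sweep over the unique
scores (higher score = predicted positive) with trapezoidal integration; the
resulting AUC equals the probability that a random positive outscores a
random negative, ties counted one half.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "metrics_from_counts",
    "roc_curve_points",
    "roc_auc",
    "repeated_kfold",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/TN/FN with positive class = interacting (label 1)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length 1-d, size >= 1")
    for name, arr in (("y_true", yt), ("y_pred", yp)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """Acc/Sen/Pre (percent) and MCC from a confusion table."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = 100.0 * (c.tp + c.tn) / c.total
    sen = 100.0 * _ratio(c.tp, c.tp + c.fn, "sensitivity")
    pre = 100.0 * _ratio(c.tp, c.tp + c.fp, "precision")
    mcc_den_sq = (
        float(c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    )
    if mcc_den_sq == 0:
        warnings.warn("MCC undefined (zero denominator); reporting NaN")
        mcc = math.nan
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_den_sq)
    return {"acc": acc, "sen": sen, "pre": pre, "mcc": mcc}


def roc_curve_points(scores, y_true) -> pd.DataFrame:
    """ROC points from a descending threshold sweep over the unique scores.

    Returns a DataFrame with columns ``fpr``, ``tpr``, ``threshold``; tied
    scores are grouped at one threshold.  Starts at (0, 0) and ends at (1, 1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y_true)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and y_true must be equal-length 1-d")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts at each distinct-score boundary
    distinct = np.r_[np.where(np.diff(s_sorted) != 0)[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted == 1)[distinct]
    fps = np.cumsum(y_sorted == 0)[distinct]
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


def roc_auc(scores, y_true) -> tuple[pd.DataFrame, float]:
    """ROC points plus the trapezoidal area under the curve."""
    pts = roc_curve_points(scores, y_true)
    auc = float(np.trapezoid(pts["tpr"].to_numpy(), pts["fpr"].to_numpy()))
    return pts, auc


def _fold_metrics(y_true, y_pred, scores) -> dict:
    out = metrics_from_counts(confusion_counts(y_true, y_pred))
    try:
        _, out["auc"] = roc_auc(scores, y_true)
    except ValueError:
        warnings.warn("AUC undefined on a single-class test fold; reporting NaN")
        out["auc"] = math.nan
    return out


def repeated_kfold(
    estimator,
    X,
    y,
    *,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    collect_roc: bool = False,
) -> dict:
    """Repeated stratified k-fold cross-validation of a classifier.

    Each repeat shuffles the data with a repeat-specific seed derived from
    ``seed``, partitions it into ``folds`` stratified near-equal parts, fits a
    clone of ``estimator`` on folds-1 parts (so any feature-extraction steps
    inside a pipeline are refit on the training part) and evaluates on the
    held-out part.  With the default 5 x 5 this yields 25 fold-level metric
    values; the summary reports mean and sd over all of them as well as
    per-repeat means.  Identical seeds give bit-identical partitions.

    Parameters
    ----------
    estimator : sklearn-style classifier (or pipeline) with decision_function
        or predict_proba for fold AUCs.
    X, y : array-likes of samples and binary labels in {0, 1}.
    folds, repeats : partition shape; defaults are the standard 5 x 5.
    seed : master seed for the repeat shuffles.
    collect_roc : also return pooled per-sample scores for ROC plotting.

    Returns
    -------
    dict with keys ``folds`` (per-fold records), ``summary`` (mean/sd over
    all folds), ``per_repeat`` (per-repeat means) and, if requested, ``roc``
    (DataFrame of pooled scores/labels from the last repeat).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    class_counts = np.unique(y, return_counts=True)[1]
    if class_counts.size < 2 or class_counts.min() < folds:
        raise ValueError(
            "need at least `folds` samples of each class for stratification"
        )
    records = []
    roc_rows = []
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    for rep, rep_seed in enumerate(repeat_seeds):
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rep_seed)
        )
        for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            model = clone(estimator).fit(X[train_idx], y[train_idx])
            y_pred = model.predict(X[test_idx])
            if hasattr(model, "decision_function"):
                scores = model.decision_function(X[test_idx])
            else:
                scores = model.predict_proba(X[test_idx])[:, 1]
            rec = {"repeat": rep, "fold": fold, "n_test": len(test_idx)}
            rec.update(_fold_metrics(y[test_idx], y_pred, scores))
            records.append(rec)
            if collect_roc and rep == repeats - 1:
                roc_rows.append(
                    pd.DataFrame({"score": scores, "label": y[test_idx]})
                )
    table = pd.DataFrame(records)
    metric_cols = ["acc", "sen", "pre", "mcc", "auc"]
    summary = {
        m: {"mean": float(table[m].mean()), "sd": float(table[m].std(ddof=1))}
        for m in metric_cols
    }
    per_repeat = [
        {key: (int(v) if key == "repeat" else float(v)) for key, v in rec.items()}
        for rec in table.groupby("repeat")[metric_cols]
        .mean()
        .reset_index()
        .to_dict("records")
    ]
    report = {
        "folds": table,
        "summary": summary,
        "per_repeat": per_repeat,
        "n_samples": int(len(y)),
        "n_folds": folds,
        "n_repeats": repeats,
        "seed": int(seed),
    }
    if collect_roc:
        report["roc"] = pd.concat(roc_rows, ignore_index=True)
    return report
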