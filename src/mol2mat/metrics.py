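"""Per-class evaluation surface: sensitivity, specificity, one-vs-rest AUC,
summary tables and one-way ANOVA across methods.

Each activity class is scored one-vs-rest: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), and AUC is the Mann-Whitney rank statistic of the
class-probability column (ties counted half).  Undefined quantities (a class
absent from the truth, or with no negatives) are reported as NaN, never as 0,
and excluded from the mean/variance rows.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "confusion_metrics",
    "auc_ovr",
    "anova_oneway",
    "class_metrics_table",
    "evaluate",
    "evaluate_prediction_table",
    "read_prediction_table",
]


def confusion_metrics(predicted, truth, positive_class) -> tuple[float, float]:
    """One-vs-rest (sensitivity, specificity) for one class.

    NaN sensitivity when the class is absent from the truth; NaN specificity
    when there are no negatives.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    pos = truth == positive_class
    hit = predicted == positive_class
    tp = int((pos & hit).sum())
    fn = int((pos & ~hit).sum())
    tn = int((~pos & ~hit).sum())
    fp = int((~pos & hit).sum())
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    return sens, spec


def auc_ovr(scores, truth, positive_class, classes=None) -> float:
    """One-vs-rest ROC AUC from class-probability rows.

    Mann-Whitney formulation on the positive-class score column, ties counted
    half; NaN when the class has no positives or no negatives.

    ``scores`` may be a (N, k) array with ``classes`` giving column order, or
    a DataFrame whose columns are class labels, or a 1-D score vector.
    """
    truth = np.asarray(truth)
    if isinstance(scores, pd.DataFrame):
        col = np.asarray(scores[positive_class], dtype=float)
    else:
        scores = np.asarray(scores, dtype=float)
        if scores.ndim == 1:
            col = scores
        else:
            if classes is None:
                raise ValueError("classes (column order) required for a score matrix")
            classes = list(classes)
            col = scores[:, classes.index(positive_class)]
    if col.shape[0] != truth.shape[0]:
        raise ValueError("scores and truth must align")
    pos = truth == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(col)  # average ranks -> ties counted half
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA over >= 2 groups of values.

    Returns (F, p) from between/within sums of squares.  When the within-group
    variance is exactly 0 with distinct means, F is reported as ``inf`` with
    p = 0 (complete separation).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = sum(g.size for g in groups) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ms_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = ms_between / ms_within
    from scipy.stats import f as f_dist

    return float(f), float(f_dist.sf(f, df_between, df_within))


def class_metrics_table(truth, predicted, scores, classes) -> pd.DataFrame:
    """Per-class sensitivity/specificity/AUC with mean and variance rows.

    Classes absent from the truth get NaN rows and are excluded from the
    summary rows.  ``scores`` is a (N, k) probability matrix in ``classes``
    column order.
    """
    rows = {}
    for cls in classes:
        sens, spec = confusion_metrics(predicted, truth, cls)
        rows[cls] = {
            "sensitivity": sens,
            "specificity": spec,
            "auc": auc_ovr(scores, truth, cls, classes=classes),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "class"
    table.loc["mean"] = table.mean(skipna=True)
    table.loc["variance"] = table.drop(index=["mean"]).var(skipna=True, ddof=1)
    return table


def evaluate(estimator, X_test, y_test) -> pd.DataFrame:
    """Score a fitted classifier on a held-out split as a per-class table."""
    scores = estimator.predict_proba(X_test)
    predicted = estimator.classes_[scores.argmax(axis=1)]
    return class_metrics_table(np.asarray(y_test), predicted, scores, list(estimator.classes_))


def read_prediction_table(path) -> pd.DataFrame:
    """Read an externally produced prediction CSV.

    Expected columns: ``molecule_id``, ``predicted_class``, then one score
    column per class named ``score_<class>``.  Used to evaluate baseline
    classifiers produced by other toolkits on the same footing.
    """
    frame = pd.read_csv(path)
    required = {"molecule_id", "predicted_class"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def evaluate_prediction_table(frame: pd.DataFrame, truth) -> pd.DataFrame:
    """Per-class metrics table from an external prediction table plus truth labels."""
    truth = np.asarray(truth).astype(str)
    score_cols = [c for c in frame.columns if c.startswith("score_")]
    classes = [c[len("score_") :] for c in score_cols]
    scores = frame[score_cols].to_numpy(dtype=float)
    predicted = frame["predicted_class"].astype(str).to_numpy()
    return class_metrics_table(truth, predicted, scores, classes)
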