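"""Leave-one-out linear-SVM discrimination of patients from controls.

Features are the significant-edge Fisher-z values selected by the NBS
stage; labels are +1 (patient) and -1 (control).  Each LOOCV fold trains a
soft-margin linear SVM on all-but-one subject and predicts the held-out
one; metrics are computed from the pooled held-out predictions, AUC from
the pooled decision values.  Significance of every metric comes from
repeating the whole LOOCV under label permutation with
p = (1 + #{null >= observed}) / (N + 1).

A feature's discriminative weight is the average of the absolute SVM
coefficient across folds; edges whose averaged absolute weight exceeds the
column mean plus one sample SD are flagged as high-contribution features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

PATIENT_LABEL = 1
CONTROL_LABEL = -1

METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auc")


@dataclass
class ClassifierResult:
    """Pooled LOOCV predictions, confusion counts, and metrics."""

    predictions: np.ndarray      # predicted +/-1 per subject
    decision_values: np.ndarray  # signed distance to the separating plane
    labels: np.ndarray
    confusion: Tuple[int, int, int, int]  # (TP, FN, TN, FP), patient positive
    metrics: Dict[str, float]
    permutation_p: Optional[Dict[str, float]] = None
    n_permutations: int = 0
    seed: Optional[int] = None


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> Dict[str, float]:
    """Classification metrics from confusion counts (patient = positive).

    accuracy = (TP+TN)/n, sensitivity = TP/(TP+FN), specificity =
    TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN).  Ratios with a zero
    denominator are NaN.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def _validate_inputs(features: np.ndarray, labels: np.ndarray) -> None:
    if features.ndim != 2:
        raise ValueError("features must be 2-D (subjects x edges)")
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree on subject count")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain missing or non-finite values")
    if not set(np.unique(labels)) <= {PATIENT_LABEL, CONTROL_LABEL}:
        raise ValueError("labels must be +1 (patient) / -1 (control)")
    if (labels == PATIENT_LABEL).sum() < 2 or (labels == CONTROL_LABEL).sum() < 2:
        raise ValueError("need >= 2 subjects per class")


def loocv_svm(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[int],
    cost: float = 1.0,
    standardize: bool = True,
) -> Tuple[ClassifierResult, np.ndarray]:
    """LOOCV linear SVM; returns the pooled result and per-fold weights.

    ``cost`` is the soft-margin penalty C.  With ``standardize`` each
    training fold's mean/SD scales both partitions (weights are then on
    the standardized-feature scale).  The returned weight array has one
    row per fold.
    """
    feat_df = isinstance(features, pd.DataFrame)
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    _validate_inputs(x, y)
    if cost <= 0:
        raise ValueError("cost must be positive")

    n, n_feat = x.shape
    preds = np.zeros(n, dtype=int)
    decf = np.zeros(n)
    weights = np.zeros((n, n_feat))
    for hold in range(n):
        tr = np.arange(n) != hold
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"training fold {hold} contains a single class")
        xtr, xte = x[tr], x[hold][None, :]
        if standardize:
            mu = xtr.mean(axis=0)
            sd = xtr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            xtr = (xtr - mu) / sd
            xte = (xte - mu) / sd
        clf = SVC(kernel="linear", C=cost)
        clf.fit(xtr, ytr)
        # sklearn orders classes ascending (-1, +1); coef_ points toward +1
        weights[hold] = clf.coef_[0]
        d = float(clf.decision_function(xte)[0])
        decf[hold] = d
        preds[hold] = PATIENT_LABEL if d > 0 else CONTROL_LABEL

    pos = y == PATIENT_LABEL
    tp = int(np.sum(preds[pos] == PATIENT_LABEL))
    fn = int(np.sum(preds[pos] == CONTROL_LABEL))
    tn = int(np.sum(preds[~pos] == CONTROL_LABEL))
    fp = int(np.sum(preds[~pos] == PATIENT_LABEL))
    metrics = metrics_from_confusion(tp, fn, tn, fp)
    metrics["auc"] = float(roc_auc_score(y, decf))
    result = ClassifierResult(
        predictions=preds,
        decision_values=decf,
        labels=y,
        confusion=(tp, fn, tn, fp),
        metrics=metrics,
    )
    return result, weights


def permutation_significance(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[int],
    n_permutations: int = 5000,
    seed: Optional[int] = None,
    cost: float = 1.0,
    standardize: bool = True,
) -> ClassifierResult:
    """LOOCV metrics plus their label-permutation p-values.

    The entire LOOCV is re-run on each of ``n_permutations`` shuffled label
    vectors; each metric's p-value is the fraction of null runs at least as
    good as observed, with the (1+b)/(N+1) correction.  Null metrics that
    are undefined (zero-denominator NaN) never count as exceedances.
    """
    rng = np.random.default_rng(seed)
    observed, _ = loocv_svm(features, labels, cost=cost, standardize=standardize)
    y = np.asarray(labels, dtype=int)
    exceed = {m: 0 for m in METRICS}
    for _ in range(n_permutations):
        perm, _ = loocv_svm(
            features, rng.permutation(y), cost=cost, standardize=standardize
        )
        for m in METRICS:
            null_v = perm.metrics[m]
            if not math.isnan(null_v) and null_v >= observed.metrics[m]:
                exceed[m] += 1
    observed.permutation_p = {
        m: (1 + exceed[m]) / (n_permutations + 1) for m in METRICS
    }
    observed.n_permutations = n_permutations
    observed.seed = seed
    return observed


def aggregate_weights(
    per_fold_weights: np.ndarray,
    edge_labels: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, float]:
    """Fold-averaged discriminative weights with the mean+1SD selection rule.

    Per edge: the mean of |w| across folds (the discriminative weight) and
    the mean signed w.  The selection threshold is the mean plus one sample
    SD (n-1 denominator) of the discriminative-weight column; edges
    strictly above it are flagged ``selected``.  Returns the table (sorted
    by rank) and the threshold.
    """
    w = np.asarray(per_fold_weights, dtype=float)
    if w.ndim == 1:
        w = w[None, :]
    if w.ndim != 2 or w.shape[0] < 1:
        raise ValueError("need a folds x edges weight matrix with >= 1 fold")
    mean_abs = np.abs(w).mean(axis=0)
    mean_signed = w.mean(axis=0)
    sd = mean_abs.std(ddof=1) if mean_abs.size > 1 else 0.0
    threshold = float(mean_abs.mean() + sd)
    if edge_labels is None:
        edge_labels = [f"edge_{k}" for k in range(w.shape[1])]
    elif len(edge_labels) != w.shape[1]:
        raise ValueError("edge_labels length != number of edges")
    order = np.argsort(-mean_abs, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    df = pd.DataFrame(
        {
            "edge": list(edge_labels),
            "mean_abs_weight": mean_abs,
            "mean_signed_weight": mean_signed,
            "rank": rank,
            "selected": mean_abs > threshold,
        }
    )
    return df.sort_values("rank").reset_index(drop=True), threshold


def top_fraction_edges(
    edge_stats: Sequence[Tuple[object, float]],
    fraction: float = 0.20,
) -> list:
    """The top-``fraction`` of edges by statistic value.

    Sorts descending by the statistic and keeps floor(fraction * count)
    edges, but at least one when the list is non-empty.  Ties are broken
    deterministically by the edge identifier.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    items = list(edge_stats)
    if not items:
        return []
    items.sort(key=lambda et: (-et[1], str(et[0])))
    k = max(1, math.floor(fraction * len(items)))
    return items[:k]
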