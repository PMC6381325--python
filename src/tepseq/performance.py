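"""Classifier performance: ROC/AUC, DeLong intervals, LOOCV, permutation null.

AUC is computed in the Mann-Whitney form -- the probability that a random
positive outscores a random negative, ties counted one half -- which makes
it exactly the normalized rank-sum statistic and lets small cases be
checked against an all-pairs enumeration.  Confidence intervals use the
DeLong placement-value variance estimator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with the midrank tie convention."""
    pos, neg = _split(np.asarray(scores, float), np.asarray(labels))
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_points(scores, labels) -> pd.DataFrame:
    """All-threshold ROC curve as (threshold, fpr, tpr) rows."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _split(scores, labels)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        rows.append((t, fpr, tpr))
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (vectorized midrank construction)."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    ranks = stats.rankdata(allv)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (ranks[:m] - rank_pos) / n          # per-positive placement
    v01 = 1.0 - (ranks[m:] - rank_neg) / m    # per-negative placement
    return v10, v01


def delong_variance(scores, labels) -> float:
    pos, neg = _split(np.asarray(scores, float), np.asarray(labels))
    v10, v01 = _placements(pos, neg)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("DeLong variance needs >= 2 samples per class")
    return float(np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong confidence interval for the AUC, truncated to [0, 1].

    Perfect separation gives zero variance and a degenerate [AUC, AUC]
    interval (with a warning) rather than an error.
    """
    auc = roc_auc(scores, labels)
    var = delong_variance(scores, labels)
    if var <= 0:
        warnings.warn("zero DeLong variance (perfect separation); degenerate CI")
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def best_accuracy(scores, labels) -> tuple[float, float]:
    """Accuracy-maximizing threshold over midpoints of adjacent unique scores.

    Calls are "positive" at ``score >= threshold``.  Ties in accuracy break
    toward the lowest threshold.  Always at least the majority-class rate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _split(scores, labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best_t, best_acc = candidates[0], -1.0
    n = labels.size
    for t in candidates:
        acc = (((scores >= t).astype(int) == labels).sum()) / n
        if acc > best_acc:
            best_t, best_acc = float(t), float(acc)
    return best_t, best_acc


def permutation_pvalue(observed_auc: float, null_aucs: np.ndarray) -> float:
    """Permutation p with the add-one correction: (1 + #{null >= obs}) / (1 + B)."""
    null_aucs = np.asarray(null_aucs, dtype=float)
    return float((1 + (null_aucs >= observed_auc).sum()) / (1 + null_aucs.size))


# ---------------------------------------------------------------------------
# Resampling procedures around a locked classifier (panel + normalization
# frozen; only the SVM support vectors are refit).  These take callables to
# avoid a circular import with the classifier module.
# ---------------------------------------------------------------------------


def loocv(
    features: pd.DataFrame,
    labels: pd.Series,
    fit_predict,
) -> pd.Series:
    """Leave-one-out cross-validation over a training cohort.

    Per round, all samples minus one train a fresh SVM (panel and
    normalization locked upstream) and the left-out sample is scored;
    every sample is predicted exactly once.  ``fit_predict(Xtr, ytr, Xte)``
    must return scores for ``Xte`` columns.
    """
    out = {}
    for s in features.columns:
        rest = [c for c in features.columns if c != s]
        score = fit_predict(features[rest], labels.loc[rest], features[[s]])
        out[s] = float(np.asarray(score)[0])
    return pd.Series(out, index=features.columns)


def permutation_null(
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    val_features: pd.DataFrame,
    val_labels: pd.Series,
    fit_predict,
    observed_auc: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Label-permutation null for a locked gene panel.

    Each replicate permutes the training class labels, refits the SVM, and
    records the validation AUC; the p-value uses the add-one estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = train_labels.to_numpy()
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = pd.Series(rng.permutation(y), index=train_labels.index)
        scores = fit_predict(train_features, perm, val_features)
        null[b] = roc_auc(scores, val_labels.to_numpy())
    return permutation_pvalue(observed_auc, null), null


def resample_stability(
    features: pd.DataFrame,
    labels: pd.Series,
    val_features: pd.DataFrame,
    val_labels: pd.Series,
    fit_predict,
    train_size: int,
    n_resample: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Validation AUC over random re-draws of the training cohort.

    The validation cohort and gene panel stay fixed; each replicate draws
    ``train_size`` samples (class-balanced as far as possible), refits the
    SVM, and records the validation AUC.  Returns (median, IQR, draws).
    """
    if train_size > features.shape[1]:
        raise ValueError("train_size exceeds the available samples")
    rng = np.random.default_rng(seed)
    cols = np.asarray(features.columns)
    y = labels.loc[features.columns]
    aucs = np.empty(n_resample)
    for b in range(n_resample):
        picked: list = []
        for level, frac in y.value_counts(normalize=True).items():
            pool = cols[(y == level).to_numpy()]
            k = min(int(round(frac * train_size)), pool.size)
            picked.extend(rng.choice(pool, size=max(k, 1), replace=False))
        sub = list(dict.fromkeys(picked))
        scores = fit_predict(features[sub], y.loc[sub], val_features)
        aucs[b] = roc_auc(scores, val_labels.to_numpy())
    q1, q3 = np.percentile(aucs, [25, 75])
    return float(np.median(aucs)), float(q3 - q1), aucs
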