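"""SVM severity classification with AHI-quantile labels, ROC/AUC and LOOCV.

Feature sets: "ecg" (the 11 HRV columns), "bf" (the 11 BRV columns) or
"combined" (all 22). AUC confidence intervals use DeLong's method; the
reported operating point maximizes Youden's J.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import FEATURE_NAMES, ClassificationResult, InsufficientDataError

HRV_COLUMNS = tuple(f"hrv_{n}" for n in FEATURE_NAMES)
BRV_COLUMNS = tuple(f"brv_{n}" for n in FEATURE_NAMES)
FEATURE_SETS = {
    "ecg": HRV_COLUMNS,
    "bf": BRV_COLUMNS,
    "combined": HRV_COLUMNS + BRV_COLUMNS,
}


def dichotomize(ahi_values: np.ndarray, quantile: float = 0.5) -> tuple:
    """Binary severity labels: 1 iff AHI strictly exceeds the cohort's
    ``quantile`` cut-off (ties go to the negative class).

    Returns (labels, cutoff_value).
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    ahi = np.asarray(ahi_values, dtype=float)
    if np.all(ahi == ahi[0]):
        raise ValueError("degenerate AHI distribution: all values equal")
    cutoff = float(np.quantile(ahi, quantile))
    return (ahi > cutoff).astype(int), cutoff


def _make_svm(seed: int = 0):
    # class_weight="balanced" counters the systematic per-fold imbalance of
    # LOOCV (the held-out sample's class is under-represented in training),
    # which otherwise biases null AUC well below 0.5
    return make_pipeline(StandardScaler(),
                         SVC(kernel="rbf", C=1.0, gamma="scale",
                             class_weight="balanced", random_state=seed))


def select_features(table: pd.DataFrame, feature_set: str) -> np.ndarray:
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {sorted(FEATURE_SETS)}")
    cols = [c for c in FEATURE_SETS[feature_set] if c in table.columns]
    if len(cols) != len(FEATURE_SETS[feature_set]):
        missing = set(FEATURE_SETS[feature_set]) - set(cols)
        raise ValueError(f"cohort table is missing feature columns: {sorted(missing)}")
    return table[cols].to_numpy(dtype=float)


def fit_predict_svm(X: np.ndarray, labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Fit the standardized RBF SVM and return continuous decision scores
    for the training rows (for ROC construction)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if counts.min() < 3:
        raise InsufficientDataError("need at least 3 rows per class")
    model = _make_svm(seed)
    model.fit(X, y)
    return model.decision_function(X)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Empirical ROC, Mann-Whitney AUC, DeLong 95% CI, and the
    sensitivity/specificity/confusion at the Youden-optimal threshold."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)

    # Mann-Whitney AUC via midranks (ties counted 1/2)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)

    # DeLong structural components
    v10 = (all_ranks[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - stats.rankdata(neg)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo, hi = np.clip([auc - 1.96 * se, auc + 1.96 * se], 0.0, 1.0)

    # empirical ROC by threshold sweep over the unique scores
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    fpr, tpr = [], []
    for t in thresholds:
        pred = s >= t
        tpr.append(np.sum(pred & (y == 1)) / m)
        fpr.append(np.sum(pred & (y == 0)) / n)
    roc = np.column_stack([fpr, tpr])

    j = np.array(tpr) - np.array(fpr)
    best = int(np.argmax(j))
    t_best = thresholds[best]
    pred = s >= t_best
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return {
        "auc": float(auc), "auc_ci": (float(lo), float(hi)),
        "roc_points": roc,
        "sensitivity": tp / (tp + fn), "specificity": tn / (tn + fp),
        "confusion": (tp, tn, fp, fn), "threshold": float(t_best),
    }


def loocv_scores(X: np.ndarray, labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Held-out decision scores: each row scored by a model (standardization
    refitted per fold) trained on the other n-1 rows. Folds whose training
    set collapses to one class are skipped (score NaN) with a warning."""
    y = np.asarray(labels)
    n = len(y)
    scores = np.full(n, np.nan)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {i}: single-class training set, skipped")
            continue
        model = _make_svm(seed)
        model.fit(X[train], y[train])
        scores[i] = model.decision_function(X[i:i + 1])[0]
    return scores


def classify(table: pd.DataFrame, feature_set: str = "combined",
             quantile: float = 0.5, loocv: bool = True,
             seed: int = 0) -> ClassificationResult:
    """End-to-end severity classification for one feature set."""
    labels, cutoff = dichotomize(table["ahi"].to_numpy(), quantile)
    X = select_features(table, feature_set)
    if loocv:
        if len(labels) < 10:
            raise InsufficientDataError("LOOCV needs at least 10 rows")
        scores = loocv_scores(X, labels, seed=seed)
        ok = ~np.isnan(scores)
        res = roc_auc(scores[ok], labels[ok])
    else:
        scores = fit_predict_svm(X, labels, seed=seed)
        res = roc_auc(scores, labels)
    return ClassificationResult(
        feature_set=feature_set, cutoff_quantile=quantile, cutoff_value=cutoff,
        auc=res["auc"], auc_ci=res["auc_ci"],
        sensitivity=res["sensitivity"], specificity=res["specificity"],
        confusion=res["confusion"], roc_points=res["roc_points"], loocv=loocv,
    )


def roc_plot(results: list[ClassificationResult], ax=None):
    """Overlayed ROC curves with AUC annotations (one per feature set)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"ecg": "tab:blue", "bf": "tab:red", "combined": "tab:purple"}
    for res in results:
        lab = (f"{res.feature_set}: AUC={res.auc:.2f} "
               f"[{res.auc_ci[0]:.2f}-{res.auc_ci[1]:.2f}]")
        ax.plot(res.roc_points[:, 0], res.roc_points[:, 1], "o-",
                color=colors.get(res.feature_set), ms=3, label=lab)
    ax.plot([0, 1], [0, 1], ls=":", color="gray")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    return ax
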