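"""Classifier bank, confusion-matrix metric suite, and channel ablation.

Seven classifier families are benchmarked on the TF-IDF features (all
delegated to scikit-learn / LightGBM with fixed seeds): naive Bayes,
gradient-boosted trees, support-vector, decision tree, k-nearest
neighbors, logistic regression, and random forest.  "Heard" is the
positive class throughout.

The metric suite is computed directly from the confusion counts:

    error       = (FP + FN) / N          accuracy    = (TP + TN) / N
    recall      = TP / (TP + FN)         precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)         F1 = 2 P R / (P + R)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Precision (and hence F1) is undefined for an all-negative predictor and
reported as ``None`` (rendered "-"); an MCC with a zero denominator is
reported as 0.  Log loss clips probabilities at 1e-15; AUC is the area
under the ROC curve over all probability thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .epochs import CHANNEL_SUBSETS, extract_epochs
from .features import fit_feature_matrix

__all__ = [
    "CLASSIFIER_FAMILIES",
    "SplitSpec",
    "ConfusionMatrix",
    "MetricsReport",
    "AblationResult",
    "make_classifier",
    "split",
    "train_predict",
    "confusion",
    "metrics",
    "kfold_cv",
    "run_ablation",
    "performance_table",
    "extra_metrics_table",
    "cross_subset_table",
]

CLASSIFIER_FAMILIES: tuple[str, ...] = (
    "naive_bayes",
    "gradient_boosted_trees",
    "support_vector",
    "decision_tree",
    "k_nearest_neighbor",
    "logistic_regression",
    "random_forest",
)

#: Abbreviations used in report tables.
FAMILY_LABELS: dict[str, str] = {
    "naive_bayes": "N.Bayes",
    "gradient_boosted_trees": "LGBM",
    "support_vector": "SVC",
    "decision_tree": "DTC",
    "k_nearest_neighbor": "KNC",
    "logistic_regression": "LR",
    "random_forest": "RFC",
}

_LOG_LOSS_EPS = 1e-15


@dataclass
class SplitSpec:
    """Shuffled, stratified train/test partition parameters."""

    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = True
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Derived metrics; ``None`` marks an undefined ratio (rendered "-")."""

    error: float
    accuracy: float
    recall: float | None
    precision: float | None
    specificity: float | None
    f1: float | None
    mcc: float
    log_loss: float | None = None
    auc: float | None = None


@dataclass
class AblationResult:
    channel_subset: str
    confusions: dict[str, ConfusionMatrix] = field(default_factory=dict)
    reports: dict[str, MetricsReport] = field(default_factory=dict)
    cv_scores: dict[str, list[float]] = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0


def make_classifier(family: str, seed: int = 0):
    """A fresh, seeded estimator of the requested family (library defaults)."""
    if family == "naive_bayes":
        return MultinomialNB()
    if family == "gradient_boosted_trees":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1)
    if family == "support_vector":
        return SVC(probability=True, random_state=seed)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "k_nearest_neighbor":
        return KNeighborsClassifier()
    if family == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown classifier family {family!r}; choose from {CLASSIFIER_FAMILIES}")


def split(
    features: sp.spmatrix | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    spec: SplitSpec | None = None,
):
    """Seeded shuffle + (stratified) 70/30 partition.

    Returns ``(X_train, X_test, y_train, y_test)``.  Raises when a class
    would be absent from either side.
    """
    spec = spec or SplitSpec()
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples of each class to split")
    x_tr, x_te, y_tr, y_te = train_test_split(
        features,
        labels,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        shuffle=True,
        stratify=labels if spec.stratified else None,
    )
    for side in (y_tr, y_te):
        if len(np.unique(side)) < len(classes):
            raise ValueError("a class is absent from one side of the split")
    return x_tr, x_te, y_tr, y_te


def train_predict(
    x_train,
    y_train,
    x_test,
    family: str,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on the training partition only; predict labels + P(heard) on test."""
    clf = make_classifier(family, seed=seed)
    clf.fit(x_train, np.asarray(y_train))
    y_pred = clf.predict(x_test)
    positive_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    proba = clf.predict_proba(x_test)[:, positive_col]
    return np.asarray(y_pred), np.asarray(proba)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Binary confusion counts with heard (1) as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(
    cm: ConfusionMatrix,
    y_true: Sequence[int] | None = None,
    proba: Sequence[float] | None = None,
) -> MetricsReport:
    """Full metric suite from the counts (plus log loss / AUC when
    probabilities are supplied)."""
    n = cm.n
    error = (cm.fp + cm.fn) / n
    accuracy = (cm.tp + cm.tn) / n
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    denom = math.sqrt(
        float(cm.tp + cm.fp)
        * float(cm.tp + cm.fn)
        * float(cm.tn + cm.fp)
        * float(cm.tn + cm.fn)
    )
    mcc = 0.0 if denom == 0 else (cm.tp * cm.tn - cm.fp * cm.fn) / denom

    log_loss_value = None
    auc = None
    if proba is not None:
        if y_true is None:
            raise ValueError("probabilities require the true labels")
        y = np.asarray(y_true).astype(int)
        p = np.clip(np.asarray(proba, dtype=float), _LOG_LOSS_EPS, 1 - _LOG_LOSS_EPS)
        log_loss_value = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        if len(np.unique(y)) == 2:
            auc = float(roc_auc_score(y, p))
    return MetricsReport(
        error=error,
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        specificity=specificity,
        f1=f1,
        mcc=mcc,
        log_loss=log_loss_value,
        auc=auc,
    )


def kfold_cv(
    features,
    labels,
    family: str,
    k: int = 5,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Seeded stratified k-fold accuracies and their mean.

    ``k == n_samples`` runs leave-one-out (singleton folds cannot be
    stratified); otherwise k may not exceed the minority-class count.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k == len(labels):
        folds = LeaveOneOut()
    elif k > counts.min():
        raise ValueError(f"k={k} exceeds the minority-class count {counts.min()}")
    else:
        folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accuracies: list[float] = []
    indexable = sp.csr_matrix(features) if sp.issparse(features) else np.asarray(features)
    for train_idx, test_idx in folds.split(indexable, labels):
        y_pred, _ = train_predict(
            indexable[train_idx], labels[train_idx], indexable[test_idx], family, seed=seed
        )
        accuracies.append(float(np.mean(y_pred == labels[test_idx])))
    return accuracies, float(np.mean(accuracies))


# ---------------------------------------------------------------------------
# channel ablation


def balanced_event_indices(labels: Sequence[str] | np.ndarray, seed: int) -> np.ndarray:
    """Indices of a class-balanced subsample (majority class downsampled)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    n_keep = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        keep.append(rng.choice(idx, size=n_keep, replace=False))
    return np.sort(np.concatenate(keep))


def run_ablation(
    dataset: Sequence[tuple],
    subsets: Sequence[str] = ("1-16", "1-13", "1-8"),
    spec: SplitSpec | None = None,
    families: Sequence[str] = CLASSIFIER_FAMILIES,
    window_s: float = 0.7,
    balance: bool = True,
    with_cv: Sequence[str] = ("gradient_boosted_trees",),
) -> list[AblationResult]:
    """Re-epoch, re-featurize, and benchmark every family per channel subset.

    ``dataset`` is a sequence of ``(preprocessed EEGRecording, labeled
    events)`` pairs — typically one per simulated subject.  The same event
    selection (optionally class-balanced) and the same split seed are used
    for every subset, so the only thing that varies across subsets is which
    channels feed the featurizer.  Cross-validation (``spec.cv_folds``) is
    run for the families listed in ``with_cv``.
    """
    spec = spec or SplitSpec()
    for name in subsets:
        if name not in CHANNEL_SUBSETS:
            raise ValueError(f"unknown channel subset {name!r}")

    # Event selection is decided once, on the full-channel epoch set.
    all_epochs_per_subset: dict[str, list] = {}
    for name in subsets:
        epochs = []
        for rec, events in dataset:
            epochs.extend(extract_epochs(rec, events, window_s=window_s, channel_subset=name))
        all_epochs_per_subset[name] = epochs
    n_events = {name: len(e) for name, e in all_epochs_per_subset.items()}
    if len(set(n_events.values())) != 1:
        raise RuntimeError(f"subsets disagree on usable events: {n_events}")

    ref = all_epochs_per_subset[subsets[0]]
    labels = np.array([1 if e.label == "heard" else 0 for e in ref])
    keep = balanced_event_indices(labels, seed=spec.seed) if balance else np.arange(len(labels))
    labels = labels[keep]

    results: list[AblationResult] = []
    for name in subsets:
        epochs = [all_epochs_per_subset[name][i] for i in keep]
        fm = fit_feature_matrix(epochs=epochs)
        x_tr, x_te, y_tr, y_te = split(fm.weights, labels, spec)
        result = AblationResult(channel_subset=name, n_train=len(y_tr), n_test=len(y_te))
        for family in families:
            y_pred, proba = train_predict(x_tr, y_tr, x_te, family, seed=spec.seed)
            cm = confusion(y_te, y_pred)
            result.confusions[family] = cm
            result.reports[family] = metrics(cm, y_true=y_te, proba=proba)
            if family in with_cv:
                scores, _ = kfold_cv(fm.weights, labels, family, k=spec.cv_folds, seed=spec.seed)
                result.cv_scores[family] = scores
        results.append(result)
    return results


# ---------------------------------------------------------------------------
# report tables (layout of the published benchmark tables)


def _pct(value: float | None) -> float | str:
    return "-" if value is None else round(100 * value, 1)


def performance_table(result: AblationResult) -> pd.DataFrame:
    """Counts + accuracy/error/recall/precision, one row per classifier.

    The error column is labeled "MSE(%)": for 0/1 predictions the mean
    squared error coincides with the classification error rate.
    """
    rows = []
    for family, cm in result.confusions.items():
        rep = result.reports[family]
        rows.append(
            {
                "Algorithm": FAMILY_LABELS.get(family, family),
                "TN": cm.tn,
                "FP": cm.fp,
                "FN": cm.fn,
                "TP": cm.tp,
                "Accuracy(%)": _pct(rep.accuracy),
                "MSE(%)": _pct(rep.error),
                "Recall(%)": _pct(rep.recall),
                "Precision(%)": _pct(rep.precision),
            }
        )
    return pd.DataFrame(rows)


def extra_metrics_table(result: AblationResult) -> pd.DataFrame:
    """F1 / specificity / MCC / log loss / AUC, one row per classifier."""
    rows = []
    for family, rep in result.reports.items():
        rows.append(
            {
                "Algorithm": FAMILY_LABELS.get(family, family),
                "F1(%)": _pct(rep.f1),
                "Specificity(%)": _pct(rep.specificity),
                "MCC": "-" if rep.mcc is None else round(rep.mcc, 3),
                "LogLoss": "-" if rep.log_loss is None else round(rep.log_loss, 3),
                "AUC(%)": _pct(rep.auc),
            }
        )
    return pd.DataFrame(rows)


def cross_subset_table(
    results: Sequence[AblationResult], family: str = "gradient_boosted_trees"
) -> pd.DataFrame:
    """One classifier across channel subsets (metric rows x subset columns)."""
    table: dict[str, list] = {"Metric": [
        "Accuracy (%)", "MSE (%)", "Recall (%)", "Precision (%)",
        "F1 (%)", "Specificity (%)", "MCC", "Log Loss", "AUC (%)", "CV accuracy (%)",
    ]}
    for result in results:
        rep = result.reports[family]
        cv = result.cv_scores.get(family)
        table[f"{result.channel_subset} channels"] = [
            _pct(rep.accuracy),
            _pct(rep.error),
            _pct(rep.recall),
            _pct(rep.precision),
            _pct(rep.f1),
            _pct(rep.specificity),
            round(rep.mcc, 3),
            "-" if rep.log_loss is None else round(rep.log_loss, 3),
            _pct(rep.auc),
            "-" if cv is None else round(100 * float(np.mean(cv)), 1),
        ]
    return pd.DataFrame(table)
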