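"""Data partitioning, cross-validation, classifier families and metrics.

The evaluation design mirrors the clinical study layout: a stratified 75/25
train/test split, 10-fold cross-validation on the training portion, and a
bank of nine classical classifier families run over PPG-only, ECG-only and
integrated feature sets. Heart failure ("HF") is the positive class.

Metrics come from the confusion matrix:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity =  TN / (TN + FP)
    sensitivity =  TP / (TP + FN)          (recall)
    precision   =  TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)

plus the rank-based (Mann-Whitney) area under the ROC curve from continuous
scores. Ratios with a zero denominator are reported as NaN (missing), never
as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .bayesnet import TanBayesClassifier
from .errors import InvalidParameterError
from .features import FeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "MODEL_FAMILIES",
    "POSITIVE_LABEL",
    "partition",
    "stratified_fold_assignment",
    "crossvalidate",
    "fit_predict",
    "confusion_from_predictions",
    "compute_metrics",
    "evaluate_models",
]

POSITIVE_LABEL = "HF"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    """Metrics for one classifier on one feature-set configuration."""

    model_name: str
    feature_set: str  # {"ppg", "ecg", "integrated"}
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float
    confusion: ConfusionMatrix
    cv_fold_metrics: list[dict] = field(default_factory=list)
    seed: int | None = None
    model_params: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        """Flat row in the canonical metric column order."""
        return {
            "model": self.model_name,
            "feature_set": self.feature_set,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auc": self.auc,
            "f1": self.f1,
        }


# ---------------------------------------------------------------------------
# model families
# ---------------------------------------------------------------------------

def _make_svm(seed):
    return SVC(kernel="rbf", random_state=seed)


def _make_rf(seed):
    return RandomForestClassifier(n_estimators=100, random_state=seed)


def _make_knn(seed):
    return KNeighborsClassifier()


def _make_random_tree(seed):
    return DecisionTreeClassifier(splitter="random", max_features="sqrt", random_state=seed)


def _make_adaboost(seed):
    return AdaBoostClassifier(random_state=seed)


def _make_bayesnet(seed):
    return TanBayesClassifier(random_state=seed)


def _make_tree(seed):
    return DecisionTreeClassifier(random_state=seed)


def _make_nb(seed):
    return GaussianNB()


def _make_mlp(seed):
    return MLPClassifier(hidden_layer_sizes=(50,), max_iter=300, random_state=seed)


MODEL_FAMILIES = {
    "SVM": _make_svm,
    "Random Forest": _make_rf,
    "K-NN": _make_knn,
    "Random Tree": _make_random_tree,
    "AdaBoost": _make_adaboost,
    "BayesNet": _make_bayesnet,
    "Decision Tree": _make_tree,
    "NaiveBayes": _make_nb,
    "MLP": _make_mlp,
}


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def partition(m: FeatureMatrix, train_fraction: float = 0.75,
              seed: int | None = None,
              stratified: bool = True) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split a feature matrix into disjoint, exhaustive train/test subsets.

    The training set has ``round(train_fraction * n)`` rows; under
    stratification the per-class training counts follow the class
    proportions (largest-remainder apportionment), so a 1636-row cohort at
    0.75 yields 1227 training and 409 test rows.
    """
    if not 0 < train_fraction < 1:
        raise InvalidParameterError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = m.data.index.to_numpy()
    n = ids.size
    n_train = int(round(train_fraction * n))

    if not stratified:
        perm = rng.permutation(n)
        train_ids, test_ids = ids[perm[:n_train]], ids[perm[n_train:]]
    else:
        y = m.labels.to_numpy()
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() == 0 or classes.size < 2:
            raise InvalidParameterError("stratified split needs every class non-empty")
        quotas = n_train * counts / n
        alloc = np.floor(quotas).astype(int)
        remainder = n_train - alloc.sum()
        # distribute leftover seats by largest fractional part (ties: larger class)
        frac_order = np.lexsort((-counts, -(quotas - alloc)))
        for j in range(remainder):
            alloc[frac_order[j]] += 1
        train_list, test_list = [], []
        for c, a in zip(classes, alloc):
            members = ids[y == c]
            perm = rng.permutation(members.size)
            train_list.append(members[perm[:a]])
            test_list.append(members[perm[a:]])
        train_ids = np.concatenate(train_list)
        test_ids = np.concatenate(test_list)
    return m.subset_rows(train_ids), m.subset_rows(test_ids)


def stratified_fold_assignment(labels: pd.Series | np.ndarray, folds: int,
                               seed: int | None = None) -> np.ndarray:
    """Assign each row to one of ``folds`` folds, sizes differing by <= 1.

    Rows are shuffled within class, interleaved across classes by fractional
    within-class position, then dealt round-robin — so fold sizes are exactly
    balanced and class proportions are near-equal per fold.
    """
    y = np.asarray(labels)
    n = y.size
    if folds < 2 or folds > n:
        raise InvalidParameterError("folds must be between 2 and the number of rows")
    rng = np.random.default_rng(seed)
    keys = np.empty(n)
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        perm = rng.permutation(members)
        keys[perm] = (np.arange(members.size) + rng.uniform(0, 1)) / members.size
    deal_order = np.argsort(keys, kind="stable")
    assignment = np.empty(n, dtype=int)
    assignment[deal_order] = np.arange(n) % folds
    return assignment


# ---------------------------------------------------------------------------
# fitting and metrics
# ---------------------------------------------------------------------------

def _encode(labels) -> np.ndarray:
    return (np.asarray(labels) == POSITIVE_LABEL).astype(int)


def fit_predict(train: FeatureMatrix, test: FeatureMatrix, model_name: str,
                seed: int | None = 0) -> tuple[np.ndarray, np.ndarray]:
    """Fit one model family on ``train``, predict labels and scores on ``test``.

    Scores are the decision-function output where the family provides one,
    otherwise the positive-class probability; either way larger means more
    heart-failure-like. Deterministic given the model seed.
    """
    if model_name not in MODEL_FAMILIES:
        raise InvalidParameterError(
            f"unknown model {model_name!r}; supported: {sorted(MODEL_FAMILIES)}"
        )
    if list(train.data.columns) != list(test.data.columns):
        raise InvalidParameterError("train and test must share feature columns")
    if train.normalization_state != test.normalization_state:
        raise InvalidParameterError("train and test must share normalization provenance")
    model = MODEL_FAMILIES[model_name](seed)
    X_tr = train.data.to_numpy(dtype=float)
    X_te = test.data.to_numpy(dtype=float)
    y_tr = _encode(train.labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on small folds
        model.fit(X_tr, y_tr)
        pred = model.predict(X_te)
        if hasattr(model, "decision_function"):
            scores = np.asarray(model.decision_function(X_te), dtype=float)
        else:
            scores = np.asarray(model.predict_proba(X_te), dtype=float)[:, 1]
    return np.asarray(pred, dtype=int), scores


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def rank_auc(scores: np.ndarray, y_true: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC: P(score+ > score-) + 0.5 P(equal)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(c: ConfusionMatrix, scores: np.ndarray | None = None,
                    y_true: np.ndarray | None = None) -> dict[str, float]:
    """The six evaluation metrics from a confusion matrix (+ scores for AUC)."""
    if c.total <= 0:
        raise InvalidParameterError("confusion matrix must contain at least one count")
    sens = _ratio(c.tp, c.tp + c.fn)
    prec = _ratio(c.tp, c.tp + c.fp)
    if np.isnan(sens) or np.isnan(prec) or (sens + prec) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * sens * prec / (sens + prec)
    auc = rank_auc(scores, y_true) if scores is not None and y_true is not None \
        else float("nan")
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "sensitivity": sens,
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "precision": prec,
        "f1": f1,
        "auc": auc,
    }


# ---------------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------------

def crossvalidate(train: FeatureMatrix, model_name: str, folds: int = 10,
                  seed: int | None = 0) -> list[dict]:
    """Per-fold validation metrics for one model family on the training set.

    Folds are disjoint, exhaustive and size-balanced (differ by at most one
    row). Each class must have at least ``folds`` members, except in the
    degenerate leave-one-out case ``folds == n`` where folds are singletons.
    """
    y = train.labels.to_numpy()
    n = y.size
    _, counts = np.unique(y, return_counts=True)
    if folds != n and counts.min() < folds:
        raise InvalidParameterError(
            f"smallest class ({counts.min()}) has fewer members than folds ({folds})"
        )
    assignment = stratified_fold_assignment(y, folds, seed)
    ids = train.data.index.to_numpy()
    out = []
    for f in range(folds):
        val_ids = ids[assignment == f]
        fit_ids = ids[assignment != f]
        fold_train = train.subset_rows(fit_ids)
        fold_val = train.subset_rows(val_ids)
        pred, scores = fit_predict(fold_train, fold_val, model_name, seed)
        y_val = _encode(fold_val.labels)
        metrics = compute_metrics(confusion_from_predictions(y_val, pred), scores, y_val)
        metrics["fold"] = f
        metrics["n_val"] = int(val_ids.size)
        out.append(metrics)
    return out


def evaluate_models(train: FeatureMatrix, test: FeatureMatrix,
                    feature_set: str,
                    models: Sequence[str] | None = None,
                    folds: int = 10, seed: int | None = 0,
                    run_cv: bool = True) -> list[EvaluationReport]:
    """Held-out evaluation (plus optional CV) of model families on one feature set."""
    models = list(MODEL_FAMILIES) if models is None else list(models)
    y_te = _encode(test.labels)
    reports = []
    for name in models:
        cv = crossvalidate(train, name, folds, seed) if run_cv else []
        pred, scores = fit_predict(train, test, name, seed)
        c = confusion_from_predictions(y_te, pred)
        metrics = compute_metrics(c, scores, y_te)
        model = MODEL_FAMILIES[name](seed)
        params = model.get_params() if hasattr(model, "get_params") else {}
        reports.append(EvaluationReport(
            model_name=name, feature_set=feature_set, confusion=c,
            cv_fold_metrics=cv, seed=seed, model_params=params, **metrics,
        ))
    return reports
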