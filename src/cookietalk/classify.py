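"""Classifier suite and repeated stratified 10-fold evaluation.

Seven fixed-hyperparameter models discriminate AD from HC on the
17-feature table: KNN (K=30), random forest (100 trees, depth 6), SVMs
with linear, 2nd-degree polynomial, precomputed-linear-Gram and RBF
kernels, and a small MLP (16-8 ReLU hidden layers, logistic output).
Evaluation is stratified 10-fold cross-validation repeated 10 times;
distance/kernel/net models see train-fold z-scored features (statistics
fitted on the training fold only), the forest sees raw features.  AD is
the positive class for precision/recall/F1; all metrics are percentages.
"""
from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import StratificationError

POSITIVE_LABEL = "AD"

MODEL_NAMES = (
    "knn",
    "random_forest",
    "svm_linear",
    "svm_poly",
    "svm_precomputed",
    "svm_rbf",
    "ann",
)

#: models whose input is z-scored on the training fold
_SCALED = frozenset(
    {"knn", "svm_linear", "svm_poly", "svm_precomputed", "svm_rbf", "ann"}
)


@dataclass(frozen=True)
class ModelSpec:
    """A named model with immutable, fixed hyperparameters."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")

    def build(self, seed: int):
        if self.name == "knn":
            return KNeighborsClassifier(n_neighbors=30)
        if self.name == "random_forest":
            return RandomForestClassifier(
                n_estimators=100, max_depth=6, random_state=seed
            )
        if self.name == "svm_linear":
            return SVC(kernel="linear")
        if self.name == "svm_poly":
            # inhomogeneous quadratic kernel (<x,y>*gamma + 1)^2: the
            # homogeneous form (coef0=0) is sign-blind on centered features
            return SVC(kernel="poly", degree=2, coef0=1.0)
        if self.name == "svm_precomputed":
            return SVC(kernel="precomputed")
        if self.name == "svm_rbf":
            return SVC(kernel="rbf")
        return MLPClassifier(
            hidden_layer_sizes=(16, 8),
            activation="relu",
            solver="adam",
            max_iter=200,
            early_stopping=True,
            random_state=seed,
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall and harmonic-mean F1, all in percent.

    Degenerate denominators (no predicted or no actual positives) yield 0
    with a warning rather than an exception.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (c.tp + c.tn) / c.total * 100.0
    if c.tp + c.fp == 0:
        warnings.warn("no predicted positives: precision defined as 0")
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp) * 100.0
    if c.tp + c.fn == 0:
        warnings.warn("no actual positives: recall defined as 0")
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn) * 100.0
    if precision + recall == 0:
        warnings.warn("precision and recall both 0: F1 defined as 0")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricSet(accuracy, precision, recall, f1)


def stratified_repeated_kfold(
    labels: np.ndarray, k: int = 10, repeats: int = 10, seed: int = 0
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Seeded fold plan: `repeats` lists of k (train_idx, test_idx) pairs.

    Each repeat's test folds partition the full index set with per-fold
    class proportions within one sample of the global proportions.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(np.zeros(len(labels)), labels))
    return [splits[r * k : (r + 1) * k] for r in range(repeats)]


@dataclass
class CVSummary:
    """Per-model metric means/sds over all repeat x fold results."""

    table: pd.DataFrame  # rows: model; columns: metric_mean, metric_sd, time_s
    trace: pd.DataFrame  # one row per (model, repeat, fold) with counts+metrics
    feature_names: list[str] = field(default_factory=list)

    def mean(self, model: str, metric: str) -> float:
        return float(self.table.loc[model, f"{metric}_mean"])


def _fold_eval(model_name: str, model, x_train, y_train, x_test, y_test) -> ConfusionCounts:
    if model_name in _SCALED:
        scaler = StandardScaler().fit(x_train)
        x_train = scaler.transform(x_train)
        x_test = scaler.transform(x_test)
    if model_name == "svm_precomputed":
        gram_train = x_train @ x_train.T
        gram_test = x_test @ x_train.T
        model.fit(gram_train, y_train)
        pred = model.predict(gram_test)
    else:
        model.fit(x_train, y_train)
        pred = model.predict(x_test)
    pos = y_test == POSITIVE_LABEL
    pred_pos = pred == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def evaluate_models(
    features: pd.DataFrame,
    labels: np.ndarray,
    specs: list[ModelSpec],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CVSummary:
    """Repeated stratified k-fold evaluation of every spec.

    `features` must be purely numeric and finite; each fold is
    standardized on its training part only (for the models that need it),
    fitted, and scored on its held-out part.
    """
    x = features.to_numpy(dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != len(labels):
        raise ValueError("feature/label shape mismatch")
    bad = ~np.isfinite(x)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite feature {features.columns[j]!r} for sample index {i}"
        )
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")

    plan = stratified_repeated_kfold(labels, k=k, repeats=repeats, seed=seed)
    records = []
    rows = []
    for spec in specs:
        start = time.perf_counter()
        for r, folds in enumerate(plan):
            for f, (train_idx, test_idx) in enumerate(folds):
                model = spec.build(seed)
                counts = _fold_eval(
                    spec.name,
                    model,
                    x[train_idx],
                    labels[train_idx],
                    x[test_idx],
                    labels[test_idx],
                )
                metrics = compute_metrics(counts)
                records.append(
                    {
                        "model": spec.name,
                        "repeat": r,
                        "fold": f,
                        "tp": counts.tp,
                        "tn": counts.tn,
                        "fp": counts.fp,
                        "fn": counts.fn,
                        "accuracy": metrics.accuracy,
                        "precision": metrics.precision,
                        "recall": metrics.recall,
                        "f1": metrics.f1,
                    }
                )
        elapsed = time.perf_counter() - start
        model_rows = pd.DataFrame([rec for rec in records if rec["model"] == spec.name])
        row = {"model": spec.name, "time_s": elapsed}
        for metric in ("accuracy", "precision", "recall", "f1"):
            row[f"{metric}_mean"] = float(model_rows[metric].mean())
            row[f"{metric}_sd"] = float(model_rows[metric].std(ddof=1))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")
    return CVSummary(
        table=table,
        trace=pd.DataFrame(records),
        feature_names=list(features.columns),
    )
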