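"""Classical classifiers on fused handcrafted features, evaluated by
stratified k-fold cross-validation.

Five standard classifiers are compared under one protocol: k-fold (default
10) stratified cross-validation where, within each fold, 30% of the training
portion is additionally held out as a validation set (scored for monitoring;
classifiers are fit on the remaining training records).  Features are
standardized (zero mean, unit variance) using training-fold statistics only.
Reported metrics are accuracy and macro-averaged recall/precision, in
percent, per fold and averaged over folds.

Default hyperparameters: KNN with 3 neighbors (Euclidean); random forest
with 100 trees; one-hidden-layer (100 units) ReLU MLP with the Adam
optimizer, L2 penalty 1e-4, initial learning rate 1e-3, at most 2000
iterations; AdaBoost with 50 estimators and learning rate 1; linear-kernel
SVM with C = 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import (StratifiedGroupKFold, StratifiedKFold,
                                     train_test_split)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "FoldSplit",
    "Metrics",
    "MetricsReport",
    "make_folds",
    "compute_metrics",
    "ClassicalClassifierModel",
    "CrossValResults",
]

CLASSIFIER_KINDS = ("knn", "rf", "mlp", "adaboost", "svm")

_DEFAULT_PARAMS: dict[str, dict] = {
    "knn": {"n_neighbors": 3, "metric": "euclidean"},
    "rf": {"n_estimators": 100},
    "mlp": {"hidden_layer_sizes": 100, "activation": "relu", "solver": "adam",
            "alpha": 1e-4, "learning_rate_init": 1e-3, "max_iter": 2000},
    "adaboost": {"n_estimators": 50, "learning_rate": 1.0},
    "svm": {"kernel": "linear", "C": 5.0},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier kind plus hyperparameters (JSON round-trip stable)."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}")
        merged = dict(_DEFAULT_PARAMS[self.kind])
        merged.update(self.params)
        object.__setattr__(self, "params", merged)

    def build(self, seed: int = 0):
        p = self.params
        if self.kind == "knn":
            return KNeighborsClassifier(**p)
        if self.kind == "rf":
            return RandomForestClassifier(random_state=seed, **p)
        if self.kind == "mlp":
            q = dict(p)
            if isinstance(q.get("hidden_layer_sizes"), list):
                q["hidden_layer_sizes"] = tuple(q["hidden_layer_sizes"])
            return MLPClassifier(random_state=seed, **q)
        if self.kind == "adaboost":
            return AdaBoostClassifier(random_state=seed, **p)
        return SVC(random_state=seed, **p)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "params": self.params}, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ClassifierSpec":
        d = json.loads(s)
        return cls(kind=d["kind"], params=d["params"])


@dataclass
class FoldSplit:
    """Stratified k-fold partition with per-fold train/validation/test index
    sets (validation = 30% of the training portion)."""

    folds: list[dict]  # each: {"train", "validation", "test"} index arrays
    k: int
    seed: int

    def __iter__(self):
        return iter(self.folds)


def make_folds(labels, k: int = 10, seed: int = 0, groups=None) -> FoldSplit:
    """Stratified k-fold index partition, deterministic per seed.

    ``labels`` may be a sequence of class labels or a manifest DataFrame
    with a ``class`` column.  Every class needs at least k records.  With
    ``groups`` (e.g. patient IDs) records sharing a group never straddle a
    test fold and the rest of the fold — the leakage-free protocol; the
    default is image-level splitting.
    """
    if isinstance(labels, pd.DataFrame):
        if groups is not None and isinstance(groups, str):
            groups = labels[groups].to_numpy()
        labels = labels["class"].to_numpy()
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise ValueError(
            f"classes with fewer than k={k} records: {list(too_small)}")
    if groups is None:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = skf.split(np.zeros(len(y)), y)
    else:
        sgk = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = sgk.split(np.zeros(len(y)), y, groups=np.asarray(groups))
    folds = []
    for fold_i, (trainval, test) in enumerate(split):
        strat = y[trainval]
        if np.unique(strat).size < 2 or np.bincount(
                np.unique(strat, return_inverse=True)[1]).min() < 2:
            strat = None
        train, val = train_test_split(
            trainval, test_size=0.3, stratify=strat,
            random_state=seed + 1000 * (fold_i + 1))
        folds.append({"train": np.sort(train), "validation": np.sort(val),
                      "test": np.sort(test)})
    return FoldSplit(folds=folds, k=k, seed=seed)


@dataclass
class Metrics:
    """Accuracy and macro-averaged recall/precision, in percent."""

    accuracy: float
    recall: float
    precision: float
    confusion: np.ndarray
    classes: list

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "recall": self.recall,
                "precision": self.precision}


def compute_metrics(y_true, y_pred, class_set=None) -> Metrics:
    """Accuracy (% correct) and macro recall/precision (%) with the per-class
    confusion matrix (rows = true class)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    classes = sorted(set(y_true) | set(y_pred)) if class_set is None else list(class_set)
    cm = _sk_confusion(y_true, y_pred, labels=classes).astype(float)
    acc = 100.0 * np.trace(cm) / cm.sum()
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    diag = np.diag(cm)
    recall = 100.0 * np.mean(np.divide(diag, row, out=np.zeros_like(diag), where=row > 0))
    precision = 100.0 * np.mean(np.divide(diag, col, out=np.zeros_like(diag), where=col > 0))
    return Metrics(accuracy=float(acc), recall=float(recall),
                   precision=float(precision), confusion=cm, classes=classes)


@dataclass
class CrossValResults:
    """Cross-validation results: per-fold and mean metrics, pooled confusion
    matrix, the spec that produced them and the seed."""

    spec: ClassifierSpec
    fold_metrics: list[Metrics]
    validation_accuracy: list[float]
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.fold_metrics]))

    @property
    def mean_recall(self) -> float:
        return float(np.mean([m.recall for m in self.fold_metrics]))

    @property
    def mean_precision(self) -> float:
        return float(np.mean([m.precision for m in self.fold_metrics]))

    @property
    def confusion(self) -> np.ndarray:
        return np.sum([m.confusion for m in self.fold_metrics], axis=0)

    def as_dict(self) -> dict:
        return {
            "classifier": json.loads(self.spec.to_json()),
            "seed": self.seed,
            "mean": {"accuracy": self.mean_accuracy, "recall": self.mean_recall,
                     "precision": self.mean_precision},
            "folds": [m.as_dict() for m in self.fold_metrics],
            "validation_accuracy": self.validation_accuracy,
            "confusion": self.confusion.tolist(),
            "classes": self.fold_metrics[0].classes,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.as_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    def summary(self) -> str:
        lines = [
            f"Classifier: {self.spec.kind}  (seed {self.seed}, "
            f"{len(self.fold_metrics)}-fold CV)",
            f"{'fold':>4}  {'accuracy':>9}  {'recall':>9}  {'precision':>9}",
        ]
        for i, m in enumerate(self.fold_metrics):
            lines.append(f"{i:>4}  {m.accuracy:>9.2f}  {m.recall:>9.2f}  "
                         f"{m.precision:>9.2f}")
        lines.append(f"{'mean':>4}  {self.mean_accuracy:>9.2f}  "
                     f"{self.mean_recall:>9.2f}  {self.mean_precision:>9.2f}")
        return "\n".join(lines)


class ClassicalClassifierModel:
    """A classifier spec bound to a feature matrix, fitted by cross-validation.

    Parameters
    ----------
    features : (n, p) array
        Row-aligned with ``labels``; must be finite.
    labels : sequence of class labels.
    spec : ClassifierSpec
    """

    def __init__(self, features, labels, spec: ClassifierSpec):
        X = np.asarray(features, dtype=float)
        bad = np.where(~np.isfinite(X).all(axis=1))[0]
        if bad.size:
            raise ValueError(f"non-finite features in rows {bad.tolist()}")
        y = np.asarray(labels)
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and labels are not row-aligned")
        self.X, self.y, self.spec = X, y, spec

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ClassifierSpec,
                       label_col: str = "class") -> "ClassicalClassifierModel":
        feat_cols = [c for c in df.columns
                     if c.startswith(("z_", "har_", "ch_"))]
        return cls(df[feat_cols].to_numpy(), df[label_col].to_numpy(), spec)

    def fit(self, folds: FoldSplit | None = None, k: int = 10,
            seed: int = 0, groups=None) -> CrossValResults:
        """Run the cross-validation protocol and return the results object."""
        if folds is None:
            folds = make_folds(self.y, k=k, seed=seed, groups=groups)
        classes = sorted(set(self.y))
        fold_metrics, val_acc = [], []
        for fold in folds:
            tr, va, te = fold["train"], fold["validation"], fold["test"]
            scaler = StandardScaler().fit(self.X[tr])
            clf = self.spec.build(seed=seed)
            clf.fit(scaler.transform(self.X[tr]), self.y[tr])
            val_acc.append(float(
                np.mean(clf.predict(scaler.transform(self.X[va])) == self.y[va])) * 100.0)
            pred = clf.predict(scaler.transform(self.X[te]))
            fold_metrics.append(compute_metrics(self.y[te], pred, classes))
        return CrossValResults(spec=self.spec, fold_metrics=fold_metrics,
                               validation_accuracy=val_acc, seed=seed)
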