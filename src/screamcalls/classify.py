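"""Acoustic-feature classification of vocalization types.

Mirrors the acoustic machine-learning design used for scream calls: each
sound is described by a fixed set of named acoustic features (the 88-feature
voice set in the original corpus), features are z-normalized across all
sounds, and a support vector machine with a third-order polynomial kernel
separates the 7 vocalization categories in a 1-versus-1 scheme. Accuracy is
estimated by stratified k-fold cross-validation in which every sound serves
exactly once as a test item, and by cross-classification between two
corpora (train on one, test on the other, in both directions).

The SVM itself is scikit-learn's SVC; multiclass voting over the pairwise
decisions is done here so ties break deterministically toward the lowest
class index in the documented category order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "ClassificationResult",
    "znormalize",
    "crossval_classify",
    "cross_classify",
    "cross_classify_both",
    "read_feature_table",
    "write_feature_table",
]


@dataclass(frozen=True)
class FeatureTable:
    """Sounds x named acoustic features, with class labels per sound."""

    values: np.ndarray
    sound_ids: tuple[str, ...]
    class_labels: tuple[str, ...]
    feature_names: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sound_ids", tuple(self.sound_ids))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        n, p = values.shape
        if len(self.sound_ids) != n or len(self.class_labels) != n:
            raise ValueError("sound_ids and class_labels must match row count")
        if len(self.feature_names) != p:
            raise ValueError("feature_names must match column count")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite (no missing data)")

    @property
    def categories(self) -> tuple[str, ...]:
        """Distinct class labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.class_labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "class_label", list(self.class_labels))
        df.insert(0, "sound_id", list(self.sound_ids))
        return df


@dataclass(frozen=True)
class ClassificationResult:
    """Confusion counts (rows = true, columns = predicted) plus accuracies."""

    confusion: np.ndarray
    categories: tuple[str, ...]
    fold_assignment: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=int)
        object.__setattr__(self, "confusion", conf)
        object.__setattr__(self, "categories", tuple(self.categories))
        k = len(self.categories)
        if conf.shape != (k, k) or np.any(conf < 0):
            raise ValueError("confusion must be a nonnegative KxK count matrix")

    @property
    def n_items(self) -> int:
        return int(self.confusion.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def per_class_accuracy(self) -> pd.Series:
        row_sums = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.where(row_sums > 0, np.diag(self.confusion) / row_sums, np.nan)
        return pd.Series(acc, index=list(self.categories), name="accuracy")

    @property
    def chance_level(self) -> float:
        return 1.0 / len(self.categories)

    def to_dict(self) -> dict:
        return {
            "categories": list(self.categories),
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy.to_dict(),
            "chance_level": self.chance_level,
            "fold_assignment": None
            if self.fold_assignment is None
            else self.fold_assignment.tolist(),
            "seed": self.seed,
        }


def znormalize(table: FeatureTable) -> FeatureTable:
    """Center each feature on its mean and divide by its sample SD.

    Constant features carry no information and cannot be scaled; they are
    set to all-zero with a warning.
    """
    if table.values.shape[0] < 2:
        raise ValueError("z-normalization needs at least 2 sounds")
    x = table.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = sd <= 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) set to zero: "
            + ", ".join(np.array(table.feature_names)[constant][:5]),
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    z = (x - mean) / safe_sd
    z[:, constant] = 0.0
    return replace(table, values=z, normalized=True)


def _make_svm(kernel_degree: int) -> SVC:
    # Fixed, conventional hyperparameters: C = 1, gamma = 'scale', and the
    # inhomogeneous polynomial kernel (coef0 = 1). The homogeneous variant
    # (coef0 = 0) cannot represent affine decision boundaries and fails on
    # linearly separable clusters; coef0 = 1 is also the common toolbox
    # default for polynomial kernels. Feature scaling is handled upstream
    # by znormalize.
    return SVC(
        C=1.0,
        kernel="poly",
        degree=kernel_degree,
        coef0=1.0,
        gamma="scale",
        decision_function_shape="ovo",
    )


def _ovo_predict(clf: SVC, x: np.ndarray, n_classes: int) -> np.ndarray:
    """1-vs-1 majority vote with ties broken toward the lowest class index.

    scikit-learn's ovo decision function orders pairs (0,1), (0,2), ...,
    (k-2,k-1); a positive value favors the first class of the pair.
    """
    dec = np.atleast_2d(clf.decision_function(x))
    votes = np.zeros((len(x), n_classes), dtype=int)
    col = 0
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            win_i = dec[:, col] > 0
            votes[win_i, i] += 1
            votes[~win_i, j] += 1
            col += 1
    # argmax returns the first (lowest) index on ties
    return votes.argmax(axis=1)


def _encode_labels(labels: tuple[str, ...], categories: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(categories)}
    missing = sorted(set(labels) - set(categories))
    if missing:
        raise ValueError(f"labels outside the category list: {missing}")
    return np.array([index[lab] for lab in labels], dtype=int)


def crossval_classify(
    table: FeatureTable,
    n_folds: int = 5,
    kernel_degree: int = 3,
    seed: int = 0,
    categories: tuple[str, ...] | None = None,
) -> ClassificationResult:
    """Stratified k-fold cross-validation; every sound is tested exactly once.

    Folds are stratified within each class so class balance is preserved,
    and the fold assignment is recorded in the result for reproducibility.
    """
    cats = tuple(categories) if categories is not None else table.categories
    y = _encode_labels(table.class_labels, cats)
    counts = np.bincount(y, minlength=len(cats))
    if np.any(counts < n_folds):
        small = [cats[i] for i in np.flatnonzero(counts < n_folds)]
        raise ValueError(f"classes smaller than n_folds={n_folds}: {small}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    k = len(cats)
    confusion = np.zeros((k, k), dtype=int)
    fold_assignment = np.full(len(y), -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(table.values, y)):
        clf = _make_svm(kernel_degree)
        clf.fit(table.values[train_idx], y[train_idx])
        # map libsvm's class ordering back to our category indices
        order = np.asarray(clf.classes_, dtype=int)
        pred_local = _ovo_predict(clf, table.values[test_idx], len(order))
        pred = order[pred_local]
        fold_assignment[test_idx] = fold
        np.add.at(confusion, (y[test_idx], pred), 1)
    return ClassificationResult(
        confusion=confusion, categories=cats, fold_assignment=fold_assignment, seed=seed
    )


def cross_classify(
    train_table: FeatureTable,
    test_table: FeatureTable,
    kernel_degree: int = 3,
    categories: tuple[str, ...] | None = None,
) -> ClassificationResult:
    """Fit on one full corpus and classify another with shared label vocabulary."""
    if train_table.feature_names != test_table.feature_names:
        differing = sorted(
            set(train_table.feature_names) ^ set(test_table.feature_names)
        )
        raise ValueError(f"feature names differ between tables: {differing}")
    cats = tuple(categories) if categories is not None else tuple(
        sorted(set(train_table.categories) | set(test_table.categories))
    )
    y_train = _encode_labels(train_table.class_labels, cats)
    y_test = _encode_labels(test_table.class_labels, cats)
    clf = _make_svm(kernel_degree)
    clf.fit(train_table.values, y_train)
    order = np.asarray(clf.classes_, dtype=int)
    pred = order[_ovo_predict(clf, test_table.values, len(order))]
    k = len(cats)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y_test, pred), 1)
    return ClassificationResult(confusion=confusion, categories=cats)


def cross_classify_both(
    table_a: FeatureTable,
    table_b: FeatureTable,
    kernel_degree: int = 3,
    categories: tuple[str, ...] | None = None,
) -> dict[str, ClassificationResult]:
    """Cross-classification in both directions, reported separately."""
    return {
        "a_to_b": cross_classify(table_a, table_b, kernel_degree, categories),
        "b_to_a": cross_classify(table_b, table_a, kernel_degree, categories),
    }


def write_feature_table(path: str | Path, table: FeatureTable) -> None:
    table.to_frame().to_csv(path, index=False)


def read_feature_table(path: str | Path, normalized: bool = False) -> FeatureTable:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["sound_id", "class_label"]:
        raise ValueError("feature table must start with sound_id, class_label columns")
    return FeatureTable(
        values=df.iloc[:, 2:].to_numpy(dtype=float),
        sound_ids=tuple(df["sound_id"].astype(str)),
        class_labels=tuple(df["class_label"].astype(str)),
        feature_names=tuple(df.columns[2:]),
        normalized=normalized,
    )
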