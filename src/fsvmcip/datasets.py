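"""Feature-table handling for two-class imbalanced classification.

Every estimator in this package assumes a *canonically ordered* dataset:
the ``m1`` majority/normal samples (label +1) come first, followed by the
``m2`` minority/abnormal samples (label -1).  Loaders enforce that
convention and retain the permutation back to the original row order so
predictions can be reported in file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "load_csv",
    "save_csv",
    "describe",
    "stratified_split",
    "standardize",
]


class DatasetError(ValueError):
    """Raised when a feature table violates the package's conventions."""


@dataclass
class Dataset:
    """Feature matrix plus ±1 labels in canonical (positives-first) order.

    Attributes
    ----------
    X : (N, n) float array
        One row per sample, one column per feature.
    y : (N,) int array
        +1 for the positive (majority/normal) class, -1 for the negative
        (minority/abnormal) class.
    feature_names : list of str, optional
    orig_index : (N,) int array
        ``orig_index[i]`` is the position of canonical row ``i`` in the
        input the dataset was built from.
    true_y : (N,) int array, optional
        Pre-noise ground-truth labels (synthetic data only).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None
    orig_index: np.ndarray | None = None
    true_y: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise DatasetError("X must be a 2-D matrix")
        if self.y.shape != (self.X.shape[0],):
            raise DatasetError("y must have one entry per row of X")
        if not np.isfinite(self.X).all():
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise DatasetError(f"non-finite feature value at row {i}, column {j}")
        labels = set(np.unique(self.y).tolist())
        if not labels <= {-1, 1}:
            raise DatasetError(f"labels must be in {{+1, -1}}, got {sorted(labels)}")
        if 1 not in labels or -1 not in labels:
            raise DatasetError("both classes must be non-empty")
        if self.orig_index is None:
            self.orig_index = np.arange(self.X.shape[0])
        # enforce canonical ordering (stable within class)
        if not self._is_canonical():
            order = np.argsort(self.y != 1, kind="stable")
            self.X = self.X[order]
            self.y = self.y[order]
            self.orig_index = np.asarray(self.orig_index)[order]
            if self.true_y is not None:
                self.true_y = np.asarray(self.true_y)[order]
        self.y = self.y.astype(int)

    def _is_canonical(self) -> bool:
        m1 = int(np.sum(self.y == 1))
        return bool(np.all(self.y[:m1] == 1))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def m1(self) -> int:
        """Number of positive (majority) samples."""
        return int(np.sum(self.y == 1))

    @property
    def m2(self) -> int:
        """Number of negative (minority) samples."""
        return int(np.sum(self.y == -1))

    @property
    def pos_mask(self) -> np.ndarray:
        return self.y == 1


def load_csv(
    path,
    label_column: str,
    positive_label: str | int | float,
    delimiter: str = ",",
) -> Dataset:
    """Load a labeled feature table from CSV into canonical order.

    ``positive_label`` names the value of ``label_column`` mapped to +1
    (the majority/normal class); the single other value maps to -1.
    """
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    if label_column not in df.columns:
        raise DatasetError(f"label column {label_column!r} not found in {path}")
    raw = df[label_column]
    values = raw.unique().tolist()
    if len(values) != 2:
        raise DatasetError(
            f"label column must have exactly two distinct values, got {values}"
        )
    pos = positive_label
    str_values = [str(v) for v in values]
    if pos not in values and str(pos) in str_values:
        pos = values[str_values.index(str(pos))]
    if pos not in values:
        raise DatasetError(f"positive label {positive_label!r} not among {values}")
    y = np.where(raw.to_numpy() == pos, 1, -1)

    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        numeric = pd.to_numeric(feats[col], errors="coerce")
        bad = ~np.isfinite(numeric.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DatasetError(
                f"non-numeric or missing feature value at row {row}, column {col!r}"
            )
        feats[col] = numeric
    return Dataset(
        X=feats.to_numpy(dtype=float),
        y=y,
        feature_names=list(feats.columns),
    )


def save_csv(ds: Dataset, path, label_column: str = "label") -> None:
    """Write a dataset back to CSV (canonical row order, ±1 labels)."""
    names = ds.feature_names or [f"x{j}" for j in range(ds.n_features)]
    df = pd.DataFrame(ds.X, columns=names)
    df[label_column] = ds.y
    df.to_csv(path, index=False, float_format="%.17g")


def describe(ds: Dataset) -> dict:
    """Dataset descriptor row: class counts, imbalance ratio, dimensionality."""
    ratio = ds.m1 / ds.m2
    if abs(ratio - round(ratio)) < 1e-9:
        ratio_str = f"{round(ratio)} : 1"
    else:
        ratio_str = f"{ratio:.1f} : 1"
    return {
        "n_pos": ds.m1,
        "n_neg": ds.m2,
        "ratio": ratio,
        "ratio_str": ratio_str,
        "d": ds.n_features,
    }


def stratified_split(
    ds: Dataset, n_pos_train: int, n_neg_train: int, seed: int
) -> tuple[Dataset, Dataset]:
    """Draw a train set with exact per-class counts; the complement is the test set.

    Sampling is without replacement and reproducible under ``seed``.
    """
    if n_pos_train > ds.m1:
        raise DatasetError(f"requested {n_pos_train} positives but only {ds.m1} exist")
    if n_neg_train > ds.m2:
        raise DatasetError(f"requested {n_neg_train} negatives but only {ds.m2} exist")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(ds.y == 1)
    neg_idx = np.flatnonzero(ds.y == -1)
    tr_pos = np.sort(rng.choice(pos_idx, size=n_pos_train, replace=False))
    tr_neg = np.sort(rng.choice(neg_idx, size=n_neg_train, replace=False))
    train_idx = np.concatenate([tr_pos, tr_neg])
    mask = np.zeros(ds.n_samples, dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)
    if test_idx.size == 0:
        warnings.warn("train split consumed every sample; test set is empty")

    def _subset(idx: np.ndarray) -> Dataset:
        return Dataset(
            X=ds.X[idx],
            y=ds.y[idx],
            feature_names=ds.feature_names,
            orig_index=np.asarray(ds.orig_index)[idx],
            true_y=None if ds.true_y is None else ds.true_y[idx],
        )

    train = _subset(train_idx)
    test = _subset(test_idx) if test_idx.size else None
    if test is None:
        # empty-complement edge case: return a zero-row shell sharing metadata
        test = Dataset.__new__(Dataset)
        test.X = np.empty((0, ds.n_features))
        test.y = np.empty(0, dtype=int)
        test.feature_names = ds.feature_names
        test.orig_index = np.empty(0, dtype=int)
        test.true_y = None
    return train, test


def standardize(
    train: Dataset, *others: Dataset
) -> tuple[Dataset, ...]:
    """Per-feature z-scoring using train-set statistics (opt-in; off by default
    everywhere else in the package, since the estimators consume features as-is).
    """
    mean = train.X.mean(axis=0)
    std = train.X.std(axis=0)
    std[std == 0] = 1.0

    def _apply(ds: Dataset) -> Dataset:
        return Dataset(
            X=(ds.X - mean) / std,
            y=ds.y,
            feature_names=ds.feature_names,
            orig_index=ds.orig_index,
            true_y=ds.true_y,
        )

    return tuple(_apply(d) for d in (train, *others))
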