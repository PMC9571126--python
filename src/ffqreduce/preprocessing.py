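"""Min-max scaling and the train/test split.

Features and targets are scaled to [0, 1] with x' = (x - min) / (max - min),
fit on the training rows only (configurable), and inverted back to
portions/day before prediction errors are reported.  Constant columns would
divide by zero under the formula; they are mapped to 0 on the forward
transform and restored to their constant on the inverse, which keeps the
round trip exact on every column.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MinMaxParams",
    "SplitIndices",
    "fit_minmax",
    "apply_minmax",
    "inverse_minmax",
    "split_train_test",
]


@dataclass(frozen=True)
class MinMaxParams:
    """Per-column min and max learned from training rows."""

    data_min: np.ndarray
    data_max: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "data_min", np.asarray(self.data_min, dtype=float))
        object.__setattr__(self, "data_max", np.asarray(self.data_max, dtype=float))
        if self.data_min.shape != self.data_max.shape or self.data_min.ndim != 1:
            raise ValueError("min/max must be 1-D vectors of equal length")
        if np.any(self.data_max < self.data_min):
            raise ValueError("max < min in scaling parameters")

    @property
    def n_columns(self) -> int:
        return self.data_min.shape[0]

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant (zero-range) columns."""
        return self.data_max == self.data_min

    def select(self, indices) -> "MinMaxParams":
        """Parameters restricted to a column subset (same order as indices)."""
        idx = np.asarray(indices, dtype=int)
        return MinMaxParams(self.data_min[idx], self.data_max[idx])

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return apply_minmax(matrix, self)

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        return inverse_minmax(scaled, self)


def _check_columns(matrix: np.ndarray, params: MinMaxParams) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[-1] != params.n_columns:
        raise ValueError(
            f"matrix has {matrix.shape[-1]} columns, params expect {params.n_columns}"
        )
    return matrix


def fit_minmax(train_matrix: np.ndarray) -> MinMaxParams:
    """Per-column min/max on the rows given (training rows only, no leakage)."""
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.ndim != 2 or train_matrix.size == 0:
        raise ValueError("cannot fit scaling on an empty matrix")
    return MinMaxParams(train_matrix.min(axis=0), train_matrix.max(axis=0))


def apply_minmax(matrix: np.ndarray, params: MinMaxParams) -> np.ndarray:
    """x' = (x - min) / (max - min); constant columns map to 0.

    Values outside the training range (test rows) leave [0, 1] and are not
    clipped, so the transform stays exactly invertible.
    """
    matrix = _check_columns(matrix, params)
    span = params.data_max - params.data_min
    safe = np.where(params.degenerate, 1.0, span)
    scaled = (matrix - params.data_min) / safe
    scaled[..., params.degenerate] = 0.0
    return scaled


def inverse_minmax(scaled: np.ndarray, params: MinMaxParams) -> np.ndarray:
    """Exact algebraic inverse; constant columns restore their constant."""
    scaled = _check_columns(scaled, params)
    span = params.data_max - params.data_min
    out = scaled * span + params.data_min
    out[..., params.degenerate] = params.data_min[params.degenerate]
    return out


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test row indices in a 3:1 ratio."""

    train: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "train", np.asarray(self.train, dtype=int))
        object.__setattr__(self, "test", np.asarray(self.test, dtype=int))
        n = len(self.train) + len(self.test)
        if set(self.train) & set(self.test) or set(self.train) | set(self.test) != set(range(n)):
            raise ValueError("train/test indices must partition the rows")


def split_train_test(n_rows: int, seed: int) -> SplitIndices:
    """Seeded uniform permutation; first ceil(0.75 * n) rows train."""
    if n_rows < 8:
        raise ValueError("need at least 8 rows for a 3:1 split with 5-fold CV")
    perm = np.random.default_rng(seed).permutation(n_rows)
    n_train = math.ceil(0.75 * n_rows)
    return SplitIndices(perm[:n_train], perm[n_train:])
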