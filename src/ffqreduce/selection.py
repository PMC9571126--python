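"""Cross-validated feature importance and question-subset selection.

The statically optimised arm ranks the 24 questions by a 5-fold
cross-validated importance: on each fold's training part a multi-target
linear model is fitted on all questions, a question's fold importance is the
mean absolute coefficient across targets (features and targets being min-max
scaled makes coefficients comparable), and the final importance averages the
folds.  Ties are broken by schema question order, which makes the ranking
fully deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .preprocessing import MinMaxParams, inverse_minmax
from .regression import MultiTargetRegression, MultiTargetRegressionResults, per_goal_error

__all__ = [
    "ImportanceRanking",
    "FeatureSubset",
    "cv_feature_importance",
    "select_top_n",
    "select_random_n",
    "per_goal_test_error",
]


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-question importance with a deterministic descending rank order."""

    question_ids: tuple[str, ...]   # schema order
    importances: np.ndarray         # aligned with question_ids, >= 0
    order: tuple[int, ...]          # indices into question_ids, best first

    def __post_init__(self) -> None:
        object.__setattr__(self, "importances",
                           np.asarray(self.importances, dtype=float))
        if len(self.question_ids) != len(self.importances):
            raise ValueError("importances must align with question ids")
        if sorted(self.order) != list(range(len(self.question_ids))):
            raise ValueError("order must be a permutation of all questions")

    @property
    def ranked_ids(self) -> tuple[str, ...]:
        return tuple(self.question_ids[i] for i in self.order)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "question_id": self.ranked_ids,
                "importance": self.importances[list(self.order)],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )

    @classmethod
    def from_scores(cls, question_ids: Sequence[str],
                    importances: np.ndarray) -> "ImportanceRanking":
        imp = np.asarray(importances, dtype=float)
        # stable sort on -importance keeps schema order among ties
        order = tuple(int(i) for i in np.argsort(-imp, kind="stable"))
        return cls(tuple(question_ids), imp, order)


@dataclass(frozen=True)
class FeatureSubset:
    """Selected question ids, kept in schema order for display."""

    question_ids: tuple[str, ...]
    indices: tuple[int, ...]  # positions in the schema question order

    def __post_init__(self) -> None:
        if len(set(self.question_ids)) != len(self.question_ids):
            raise ValueError("duplicate questions in subset")
        if len(self.indices) != len(self.question_ids):
            raise ValueError("indices must align with question ids")

    def __len__(self) -> int:
        return len(self.question_ids)

    @classmethod
    def from_indices(cls, all_ids: Sequence[str], indices) -> "FeatureSubset":
        idx = tuple(sorted(int(i) for i in indices))
        return cls(tuple(all_ids[i] for i in idx), idx)


def cv_feature_importance(X_train: np.ndarray, Y_train: np.ndarray,
                          question_ids: Sequence[str], k: int = 5,
                          seed: int = 0) -> ImportanceRanking:
    """Fold-averaged mean absolute coefficient per question.

    Rows are partitioned into ``k`` seeded folds; each fold's importance is
    computed from a model fitted on the complementary training part using all
    questions.  Linear in Y: rescaling a target column rescales its
    contribution to the importance, which is exactly how the personalised
    weighting steers the ranking.
    """
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    if Y_train.ndim == 1:
        Y_train = Y_train[:, None]
    if k < 2:
        raise ValueError("need at least 2 folds")
    if X_train.shape[0] < k:
        raise ValueError(f"{X_train.shape[0]} rows cannot form {k} folds")
    if X_train.shape[1] != len(question_ids):
        raise ValueError("X columns must match question ids")

    kfold = KFold(n_splits=k, shuffle=True, random_state=seed)
    importance = np.zeros(X_train.shape[1])
    for fold_train, _ in kfold.split(X_train):
        results = MultiTargetRegression(
            X_train[fold_train], Y_train[fold_train]
        ).fit()
        importance += np.abs(results.coef).mean(axis=0)
    importance /= k
    return ImportanceRanking.from_scores(question_ids, importance)


def select_top_n(ranking: ImportanceRanking, n: int) -> FeatureSubset:
    """The n most important questions, re-ordered to schema order."""
    if not 1 <= n <= len(ranking.question_ids):
        raise ValueError(f"n must be in 1..{len(ranking.question_ids)}, got {n}")
    return FeatureSubset.from_indices(ranking.question_ids, ranking.order[:n])


def select_random_n(question_ids: Sequence[str], n: int, seed: int) -> FeatureSubset:
    """Uniform sample of n questions without replacement, seeded."""
    if not 1 <= n <= len(question_ids):
        raise ValueError(f"n must be in 1..{len(question_ids)}, got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(question_ids), size=n, replace=False)
    return FeatureSubset.from_indices(question_ids, idx)


def per_goal_test_error(results: MultiTargetRegressionResults,
                        X_test: np.ndarray, Y_test: np.ndarray,
                        target_params: MinMaxParams,
                        metric: str = "mae") -> np.ndarray:
    """Per-goal test error in portions/day.

    Predictions and truths are inverse-scaled back to the portions-per-day
    scale before the error is taken, so errors are comparable across goals
    and directly interpretable against the thresholds.
    """
    Y_test = np.asarray(Y_test, dtype=float)
    if Y_test.ndim == 1:
        Y_test = Y_test[:, None]
    if Y_test.shape[0] == 0:
        raise ValueError("empty test set")
    pred = results.predict(X_test)
    return per_goal_error(
        inverse_minmax(Y_test, target_params),
        inverse_minmax(pred, target_params),
        metric=metric,
    )
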