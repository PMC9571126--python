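"""Personalised question selection from predicted threshold violations.

The personalised arm runs in two steps.  Step 1 is the static pipeline:
cross-validated importance on the activated goals, top-n questions, a model
fitted on them, and predictions for the evaluation rows.  Step 2 measures how
far each predicted quality score violates its threshold,

    dist(y_pred, y_opt) = max((y_pred - y_opt) * y_adj, 0),

with y_adj = +1 for at-most goals and -1 for at-least goals, so only actual
violations count; the distances are scaled to [0, 1] (divide by the maximum)
and used as weights on the target columns before the importance is
recomputed.  Because a multi-target OLS fit is separable per target, the
weights change nothing about any single target's fit — their entire effect is
to steer the importance ranking toward the questions feeding the most
violated goals.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocessing import MinMaxParams, apply_minmax
from .regression import MultiTargetRegression
from .schema import FFQSchema
from .selection import (
    FeatureSubset,
    ImportanceRanking,
    cv_feature_importance,
    select_top_n,
)

__all__ = [
    "ThresholdVector",
    "distance_to_threshold",
    "distances_to_weights",
    "reweight_targets",
    "personalised_selection",
    "PersonalisedSelection",
]

DEFAULT_WEIGHT_FLOOR = 0.05


@dataclass(frozen=True)
class ThresholdVector:
    """Per-activated-goal thresholds (y_opt) and adjustment signs (y_adj)."""

    goal_ids: tuple[str, ...]
    y_opt: np.ndarray
    y_adj: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y_opt", np.asarray(self.y_opt, dtype=float))
        object.__setattr__(self, "y_adj", np.asarray(self.y_adj, dtype=float))
        if not (len(self.goal_ids) == len(self.y_opt) == len(self.y_adj)):
            raise ValueError("goal ids, y_opt and y_adj must align")
        if not np.all(np.isin(self.y_adj, (-1.0, 1.0))):
            raise ValueError("y_adj entries must be -1 or +1")

    @classmethod
    def from_schema(cls, schema: FFQSchema, goal_ids: Sequence[str],
                    target_params: MinMaxParams | None = None) -> "ThresholdVector":
        """Thresholds for the activated goals, optionally in scaled space.

        Passing the target scaling parameters maps each threshold through the
        same min-max transform as the quality scores, so predicted scores and
        thresholds are commensurable.
        """
        y_opt = schema.thresholds(goal_ids)
        if target_params is not None:
            y_opt = apply_minmax(y_opt[None, :], target_params)[0]
        return cls(tuple(goal_ids), y_opt, schema.adjustment_signs(goal_ids))


def distance_to_threshold(y_pred: np.ndarray,
                          thresholds: ThresholdVector) -> np.ndarray:
    """max((y_pred - y_opt) * y_adj, 0): zero exactly when the goal is met."""
    y_pred = np.asarray(y_pred, dtype=float)
    if y_pred.shape[-1] != len(thresholds.goal_ids):
        raise ValueError(
            f"predicted {y_pred.shape[-1]} goals, thresholds for "
            f"{len(thresholds.goal_ids)}"
        )
    return np.maximum((y_pred - thresholds.y_opt) * thresholds.y_adj, 0.0)


def distances_to_weights(dist: np.ndarray, floor: float = DEFAULT_WEIGHT_FLOOR,
                         scaling: str = "max") -> np.ndarray:
    """Scale violation distances to [0, 1] goal weights.

    ``scaling='max'`` divides by the largest distance, so the most violated
    goal gets weight 1 and satisfied goals keep the floor weight rather than
    vanishing from the regression.  ``scaling='minmax'`` is the alternative
    reading (least-violated goal pinned at the floor).  With no violation at
    all, every goal weighs 1 and personalised selection reduces to the static
    one.
    """
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    if not 0 <= floor <= 1:
        raise ValueError("floor must be in [0, 1]")
    top = dist.max()
    if top == 0:
        return np.ones_like(dist)
    if scaling == "max":
        weights = dist / top
    elif scaling == "minmax":
        span = top - dist.min()
        weights = (dist - dist.min()) / span if span > 0 else np.ones_like(dist)
    else:
        raise ValueError(f"unknown weight scaling {scaling!r}")
    return np.maximum(weights, floor)


def reweight_targets(Y_scaled: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Multiply each target column by its goal weight."""
    Y_scaled = np.asarray(Y_scaled, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if Y_scaled.shape[-1] != weights.shape[0]:
        raise ValueError(
            f"{Y_scaled.shape[-1]} target columns vs {weights.shape[0]} weights"
        )
    return Y_scaled * weights


@dataclass(frozen=True)
class PersonalisedSelection:
    """Output of the two-step personalised pipeline."""

    subset: FeatureSubset          # step-2 (personalised) questions
    weights: np.ndarray            # per-activated-goal weights in [floor, 1]
    static_subset: FeatureSubset   # step-1 (equal-importance) questions
    distances: np.ndarray          # scaled-space violation distances
    static_ranking: ImportanceRanking
    personalised_ranking: ImportanceRanking


def personalised_selection(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_eval: np.ndarray,
    schema: FFQSchema,
    active_goal_ids: Sequence[str],
    n: int,
    target_params: MinMaxParams,
    cv_folds: int = 5,
    fold_seed: int = 0,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    weight_scaling: str = "max",
    mode: str = "population",
    user_index: int | None = None,
) -> PersonalisedSelection:
    """Two-step personalised question selection.

    Parameters
    ----------
    X_train, Y_train : arrays
        Scaled training features (all questions) and scaled activated-goal
        targets.
    X_eval : array
        Scaled feature rows whose predicted scores drive the weights — the
        held-out evaluation rows in the experiments, or a user's own previous
        answers in the app setting.
    mode : {'population', 'user'}
        ``population`` averages predicted scores over the evaluation rows;
        ``user`` takes the single row ``user_index``.
    """
    if len(active_goal_ids) == 0:
        raise ValueError("need at least one activated goal")
    Y_train = np.asarray(Y_train, dtype=float)
    if Y_train.ndim == 1:
        Y_train = Y_train[:, None]
    if Y_train.shape[1] != len(active_goal_ids):
        raise ValueError("Y_train columns must match activated goals")

    # step 1: static pipeline on equally-important activated goals
    static_ranking = cv_feature_importance(
        X_train, Y_train, schema.question_ids, k=cv_folds, seed=fold_seed
    )
    static_subset = select_top_n(static_ranking, n)
    step1 = MultiTargetRegression(
        X_train[:, static_subset.indices], Y_train,
        feature_names=static_subset.question_ids,
        target_names=active_goal_ids,
    ).fit()
    y_pred = step1.predict(np.asarray(X_eval, dtype=float)[:, static_subset.indices])
    if mode == "population":
        scores = y_pred.mean(axis=0)
    elif mode == "user":
        if user_index is None or not 0 <= user_index < y_pred.shape[0]:
            raise ValueError("mode='user' needs a valid user_index")
        scores = y_pred[user_index]
    else:
        raise ValueError(f"unknown personalisation mode {mode!r}")

    # step 2: violations -> weights -> reweighted importance
    thresholds = ThresholdVector.from_schema(schema, active_goal_ids, target_params)
    distances = distance_to_threshold(scores, thresholds)
    weights = distances_to_weights(distances, floor=weight_floor,
                                   scaling=weight_scaling)
    personalised_ranking = cv_feature_importance(
        X_train, reweight_targets(Y_train, weights), schema.question_ids,
        k=cv_folds, seed=fold_seed,
    )
    subset = select_top_n(personalised_ranking, n)
    return PersonalisedSelection(
        subset=subset,
        weights=weights,
        static_subset=static_subset,
        distances=distances,
        static_ranking=static_ranking,
        personalised_ranking=personalised_ranking,
    )
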