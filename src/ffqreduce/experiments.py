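"""Three-arm question-reduction experiments.

Compares, over seeds, feature counts and activated-goal combinations, three
ways of choosing which n of the 24 questions to keep:

* ``random`` — a seeded uniform subset (baseline);
* ``static`` — cross-validated feature importance with all activated goals
  treated as equally important;
* ``personalised`` — importance recomputed after weighting each activated
  goal by how far its predicted score violates its threshold.

In every arm the final model is refit on the training rows restricted to the
selected questions and evaluated once on the held-out quarter; errors are
reported in portions/day per activated goal.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .personalize import DEFAULT_WEIGHT_FLOOR, personalised_selection
from .preprocessing import MinMaxParams, apply_minmax, fit_minmax, split_train_test
from .regression import MultiTargetRegression
from .schema import FFQSchema, ResponseMatrix, compute_quality_scores, default_schema
from .selection import (
    FeatureSubset,
    cv_feature_importance,
    per_goal_test_error,
    select_random_n,
    select_top_n,
)
from .simulate import default_population, simulate_responses

__all__ = [
    "ARMS",
    "ExperimentConfig",
    "ExperimentResult",
    "ArmResult",
    "enumerate_goal_combinations",
    "sample_goal_combinations",
    "stratified_combination_panel",
    "prepare_seed_data",
    "run_arm",
    "run_sweep",
    "aggregate_by_active_count",
]

logger = logging.getLogger(__name__)

ARMS = ("random", "static", "personalised")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a sweep needs to be reproducible from a single seed list."""

    arms: tuple[str, ...] = ARMS
    feature_counts: tuple[int, ...] = (4, 6, 9, 12)
    combinations: tuple[tuple[str, ...], ...] | None = None
    n_combinations: int = 60       # stratified sample size when combinations is None
    min_active: int = 2
    n_users: int = 1000
    seeds: tuple[int, ...] = (0,)
    error_metric: str = "mae"      # or "rmse"
    weight_floor: float = DEFAULT_WEIGHT_FLOOR
    weight_scaling: str = "max"    # or "minmax"
    scaling_scope: str = "train"   # or "all"
    cv_folds: int = 5
    personalisation_mode: str = "population"

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("config: at least one arm")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"config: unknown arms {sorted(unknown)}")
        if not self.feature_counts:
            raise ValueError("config: at least one feature count")
        if not self.seeds:
            raise ValueError("config: at least one seed")
        if self.scaling_scope not in ("train", "all"):
            raise ValueError("config: scaling_scope must be 'train' or 'all'")


def enumerate_goal_combinations(goals: Sequence[str] | int,
                                min_active: int = 2) -> list[tuple]:
    """All activated-goal subsets of size >= min_active, lexicographic.

    For the default 11 goals at min_active=2 this yields
    2^11 - 1 - 11 = 2036 combinations.
    """
    if isinstance(goals, int):
        goals = tuple(range(goals))
    n = len(goals)
    if not 1 <= min_active <= n:
        raise ValueError(f"min_active must be in 1..{n}, got {min_active}")
    out: list[tuple] = []
    for size in range(min_active, n + 1):
        out.extend(itertools.combinations(goals, size))
    return out


def sample_goal_combinations(goals: Sequence[str], n_samples: int, seed: int,
                             min_active: int = 2) -> list[tuple]:
    """Sample combinations stratified by activated-set size.

    Slots are allocated round-robin over sizes min_active..len(goals) so every
    size is represented; within a size, subsets are drawn uniformly without
    replacement.  Deterministic per seed.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    by_size: dict[int, list[tuple]] = {}
    for combo in enumerate_goal_combinations(goals, min_active):
        by_size.setdefault(len(combo), []).append(combo)
    sizes = sorted(by_size)
    total = sum(len(v) for v in by_size.values())
    if n_samples >= total:
        return [c for s in sizes for c in by_size[s]]

    rng = np.random.default_rng(seed)
    quota = {s: 0 for s in sizes}
    remaining = n_samples
    while remaining > 0:
        for s in sizes:
            if remaining == 0:
                break
            if quota[s] < len(by_size[s]):
                quota[s] += 1
                remaining -= 1
    chosen = []
    for s in sizes:
        pool = by_size[s]
        idx = rng.choice(len(pool), size=quota[s], replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return chosen


def stratified_combination_panel(goals: Sequence[str], n_combinations: int = 20,
                                 min_active: int = 2) -> list[tuple[str, ...]]:
    """A deterministic, balanced panel of activated-goal combinations.

    Slots are allocated round-robin over set sizes min_active..len(goals);
    within a size the combinations are contiguous cyclic blocks of the goal
    order at evenly spaced offsets.  Every goal therefore appears equally
    often (up to rounding) within each size stratum, which removes the
    goal-composition variance that random sampling injects into means taken
    per activated-set size.  Used for trend analyses; ``sample_goal_combinations``
    remains the random alternative.
    """
    n = len(goals)
    if n_combinations <= 0:
        raise ValueError("n_combinations must be positive")
    sizes = list(range(min_active, n + 1))
    max_distinct = {s: (1 if s == n else n) for s in sizes}
    counts = {s: 0 for s in sizes}
    remaining = n_combinations
    while remaining > 0:
        progressed = False
        for s in sizes:
            if remaining == 0:
                break
            if counts[s] < max_distinct[s]:
                counts[s] += 1
                remaining -= 1
                progressed = True
        if not progressed:
            break
    panel: list[tuple[str, ...]] = []
    for s in sizes:
        m = counts[s]
        for k in range(m):
            offset = (k * n) // m
            block = tuple(sorted(goals[(offset + j) % n] for j in range(s)))
            panel.append(block)
    return panel


def derive_subseeds(seed: int) -> dict[str, int]:
    """Independent sub-seeds for the generator, split, folds and random arm.

    One experiment seed drives four independent streams so the three arms are
    compared on identical data and splits while the random arm's subsets stay
    independent of them.
    """
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("generator", "split", "folds", "random_arm")
    return {
        name: int(child.generate_state(1)[0] % (2 ** 31))
        for name, child in zip(names, children)
    }


@dataclass(frozen=True)
class SeedData:
    """Scaled train/test data shared by every arm at one experiment seed."""

    schema: FFQSchema
    X_train: np.ndarray   # scaled, all questions
    X_test: np.ndarray
    Y_train: np.ndarray   # scaled, all goals
    Y_test: np.ndarray
    feature_params: MinMaxParams  # all questions
    target_params: MinMaxParams   # all goals
    subseeds: dict[str, int]


def prepare_seed_data(responses: ResponseMatrix, schema: FFQSchema,
                      seed: int, config: ExperimentConfig) -> SeedData:
    """Score, split 3:1 and min-max scale one dataset for one seed."""
    scores = compute_quality_scores(responses, schema)
    subseeds = derive_subseeds(seed)
    split = split_train_test(responses.n_users, subseeds["split"])
    X, Y = responses.values, scores.values
    fit_rows_X = X if config.scaling_scope == "all" else X[split.train]
    fit_rows_Y = Y if config.scaling_scope == "all" else Y[split.train]
    feature_params = fit_minmax(fit_rows_X)
    target_params = fit_minmax(fit_rows_Y)
    return SeedData(
        schema=schema,
        X_train=apply_minmax(X[split.train], feature_params),
        X_test=apply_minmax(X[split.test], feature_params),
        Y_train=apply_minmax(Y[split.train], target_params),
        Y_test=apply_minmax(Y[split.test], target_params),
        feature_params=feature_params,
        target_params=target_params,
        subseeds=subseeds,
    )


@dataclass(frozen=True)
class ArmResult:
    """Per-goal test errors for one (arm, n, active set) cell."""

    arm: str
    n_features: int
    active_goal_ids: tuple[str, ...]
    errors: np.ndarray            # portions/day, aligned with active_goal_ids
    subset: FeatureSubset
    weights: np.ndarray | None    # personalised arm only


def run_arm(arm: str, n_features: int, active_goal_ids: Sequence[str],
            data: SeedData, config: ExperimentConfig) -> ArmResult:
    """Select questions by the arm's rule, refit, evaluate on the test set."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    schema = data.schema
    act_idx = schema.goal_indices(active_goal_ids)
    Yt = data.Y_train[:, act_idx]
    Yv = data.Y_test[:, act_idx]
    tparams = data.target_params.select(act_idx)
    weights = None

    if arm == "random":
        # subset seed varies with n so different grid sizes are independent
        rand_seed = np.random.default_rng(
            [data.subseeds["random_arm"], n_features]
        ).integers(2 ** 31)
        subset = select_random_n(schema.question_ids, n_features, int(rand_seed))
    elif arm == "static":
        ranking = cv_feature_importance(
            data.X_train, Yt, schema.question_ids,
            k=config.cv_folds, seed=data.subseeds["folds"],
        )
        subset = select_top_n(ranking, n_features)
    else:
        selection = personalised_selection(
            data.X_train, Yt, data.X_test, schema, tuple(active_goal_ids),
            n_features, tparams,
            cv_folds=config.cv_folds, fold_seed=data.subseeds["folds"],
            weight_floor=config.weight_floor,
            weight_scaling=config.weight_scaling,
            mode=config.personalisation_mode,
        )
        subset = selection.subset
        weights = selection.weights

    results = MultiTargetRegression(
        data.X_train[:, subset.indices], Yt,
        feature_names=subset.question_ids, target_names=tuple(active_goal_ids),
    ).fit()
    errors = per_goal_test_error(
        results, data.X_test[:, subset.indices], Yv, tparams,
        metric=config.error_metric,
    )
    return ArmResult(arm, n_features, tuple(active_goal_ids), errors, subset, weights)


@dataclass(frozen=True)
class ExperimentResult:
    """Tidy per-(arm, n, combination, seed, goal) error records."""

    records: pd.DataFrame
    config: ExperimentConfig

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @property
    def n_failures(self) -> int:
        return int((self.records["status"] != "ok").sum())

    def aggregate_by_active_count(self) -> pd.DataFrame:
        return aggregate_by_active_count(self)


RECORD_COLUMNS = ("arm", "n_features", "active_set", "n_active", "seed",
                  "goal", "error", "weight", "status")


def run_sweep(config: ExperimentConfig, schema: FFQSchema | None = None,
              responses: ResponseMatrix | None = None) -> ExperimentResult:
    """Full factorial over arms x feature counts x combinations x seeds.

    With ``responses=None`` each seed simulates a fresh default population of
    ``config.n_users`` users; passing a fixed response matrix reuses it for
    every seed (only splits, folds and the random arm then vary).  A failing
    cell becomes a ``status='failed'`` record instead of aborting the sweep.
    """
    schema = schema or default_schema()
    if config.combinations is not None:
        combos = [tuple(c) for c in config.combinations]
    else:
        combos = sample_goal_combinations(
            schema.goal_ids, config.n_combinations,
            seed=min(config.seeds), min_active=config.min_active,
        )
    rows: list[dict] = []
    for seed in config.seeds:
        if responses is None:
            spec = default_population(
                config.n_users, derive_subseeds(seed)["generator"], schema
            )
            seed_responses = simulate_responses(spec, schema)
        else:
            seed_responses = responses
        data = prepare_seed_data(seed_responses, schema, seed, config)
        for combo in combos:
            for n in config.feature_counts:
                for arm in config.arms:
                    try:
                        res = run_arm(arm, n, combo, data, config)
                    except Exception as exc:  # record, don't crash the sweep
                        logger.warning("cell failed: %s n=%d %s seed=%d: %s",
                                       arm, n, combo, seed, exc)
                        for goal in combo:
                            rows.append(dict(
                                arm=arm, n_features=n, active_set="+".join(combo),
                                n_active=len(combo), seed=seed, goal=goal,
                                error=np.nan, weight=np.nan, status="failed",
                            ))
                        continue
                    for i, goal in enumerate(combo):
                        rows.append(dict(
                            arm=arm, n_features=n, active_set="+".join(combo),
                            n_active=len(combo), seed=seed, goal=goal,
                            error=float(res.errors[i]),
                            weight=(float(res.weights[i])
                                    if res.weights is not None else np.nan),
                            status="ok",
                        ))
        logger.info("seed %d done (%d records)", seed, len(rows))
    records = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    return ExperimentResult(records=records, config=config)


def aggregate_by_active_count(result: ExperimentResult | pd.DataFrame) -> pd.DataFrame:
    """Mean portions/day error keyed by (arm, n_features, n_active).

    Averages over combinations of the same activated-set size, over seeds and
    over the activated goals, mirroring how the sweep results are reported.
    """
    df = result.records if isinstance(result, ExperimentResult) else result
    if df.empty:
        raise ValueError("no records to aggregate")
    ok = df[df["status"] == "ok"]
    return (
        ok.groupby(["arm", "n_features", "n_active"], as_index=False)["error"]
        .mean()
        .sort_values(["arm", "n_features", "n_active"], ignore_index=True)
    )
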