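"""Questionnaire structure and scoring.

A grid-style Food Frequency Questionnaire (FFQ) asks about daily portions of
24 food items ("questions").  Answers are summarised into quality scores for
11 nutrition aspects ("goals"), each compared against a portions-per-day
threshold that must either be reached (at least) or not over-reached
(at most).  This module defines the schema types, loads/validates schema
files, and computes goal quality scores from a response table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Direction",
    "Question",
    "Goal",
    "FFQSchema",
    "ResponseMatrix",
    "QualityScores",
    "SchemaError",
    "load_schema",
    "save_schema",
    "default_schema",
    "compute_quality_scores",
]


class SchemaError(ValueError):
    """A questionnaire schema violates one of its invariants."""


class Direction(str, Enum):
    """Whether a goal's threshold must be reached or not exceeded."""

    AT_LEAST = "at_least"
    AT_MOST = "at_most"

    @property
    def sign(self) -> int:
        """Threshold-adjustment sign: +1 for at-most, -1 for at-least.

        A positive signed difference (predicted - threshold) * sign means the
        goal is violated: the user over-reaches an at-most threshold or falls
        short of an at-least one.
        """
        return 1 if self is Direction.AT_MOST else -1


@dataclass(frozen=True)
class Question:
    """A single food-item question on the grid."""

    id: str
    label: str
    portion_unit: str = "portions/day"


@dataclass(frozen=True)
class Goal:
    """A nutrition aspect scored from one or more questions."""

    id: str
    label: str
    threshold: float
    direction: Direction
    questions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise SchemaError(f"goal {self.id!r}: threshold must be >= 0")
        if not self.questions:
            raise SchemaError(f"goal {self.id!r}: needs >= 1 contributing question")


@dataclass(frozen=True)
class FFQSchema:
    """Ordered questions and goals; question order is the tie-break order."""

    questions: tuple[Question, ...]
    goals: tuple[Goal, ...]

    def __post_init__(self) -> None:
        qids = [q.id for q in self.questions]
        if len(set(qids)) != len(qids):
            dup = sorted({q for q in qids if qids.count(q) > 1})
            raise SchemaError(f"duplicate question ids: {dup}")
        gids = [g.id for g in self.goals]
        if len(set(gids)) != len(gids):
            dup = sorted({g for g in gids if gids.count(g) > 1})
            raise SchemaError(f"duplicate goal ids: {dup}")
        known = set(qids)
        for g in self.goals:
            missing = [q for q in g.questions if q not in known]
            if missing:
                raise SchemaError(
                    f"goal {g.id!r}: unknown question reference {missing}"
                )

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self.questions)

    @property
    def goal_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.goals)

    @property
    def n_questions(self) -> int:
        return len(self.questions)

    @property
    def n_goals(self) -> int:
        return len(self.goals)

    def question_index(self, qid: str) -> int:
        try:
            return self.question_ids.index(qid)
        except ValueError:
            raise KeyError(f"unknown question id {qid!r}") from None

    def goal(self, gid: str) -> Goal:
        for g in self.goals:
            if g.id == gid:
                return g
        raise KeyError(f"unknown goal id {gid!r}")

    def mapping_matrix(self) -> np.ndarray:
        """0/1 matrix M (goals x questions): scores = responses @ M.T."""
        m = np.zeros((self.n_goals, self.n_questions))
        for i, g in enumerate(self.goals):
            for q in g.questions:
                m[i, self.question_index(q)] = 1.0
        return m

    def thresholds(self, goal_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.goal_ids if goal_ids is None else goal_ids
        return np.array([self.goal(g).threshold for g in ids], dtype=float)

    def adjustment_signs(self, goal_ids: Sequence[str] | None = None) -> np.ndarray:
        """Per-goal sign vector: +1 for at-most goals, -1 for at-least."""
        ids = self.goal_ids if goal_ids is None else goal_ids
        return np.array([self.goal(g).direction.sign for g in ids], dtype=float)

    def goal_indices(self, goal_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.goal_ids.index(g) for g in goal_ids], dtype=int)


def _as_user_table(user_ids, values, column_ids, kind: str) -> None:
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"{kind}: values must be 2-D")
    if len(user_ids) != values.shape[0]:
        raise ValueError(f"{kind}: {len(user_ids)} user ids vs {values.shape[0]} rows")
    if len(column_ids) != values.shape[1]:
        raise ValueError(
            f"{kind}: {len(column_ids)} column ids vs {values.shape[1]} columns"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{kind}: missing or non-finite values")
    if np.any(values < 0):
        raise ValueError(f"{kind}: negative values")


@dataclass(frozen=True)
class ResponseMatrix:
    """Users x questions table of portions/day answers."""

    user_ids: tuple
    question_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _as_user_table(self.user_ids, self.values, self.question_ids, "responses")

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.question_ids))
        df.insert(0, "user_id", list(self.user_ids))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, schema: FFQSchema) -> "ResponseMatrix":
        if "user_id" not in df.columns:
            raise ValueError("responses: missing 'user_id' column")
        missing = [q for q in schema.question_ids if q not in df.columns]
        if missing:
            raise ValueError(f"responses: missing question columns {missing}")
        values = df[list(schema.question_ids)].to_numpy(dtype=float)
        return cls(tuple(df["user_id"]), schema.question_ids, values)

    @classmethod
    def read_csv(cls, path: str | Path, schema: FFQSchema) -> "ResponseMatrix":
        return cls.from_frame(pd.read_csv(path), schema)


@dataclass(frozen=True)
class QualityScores:
    """Users x goals table of portions/day-scale quality scores."""

    user_ids: tuple
    goal_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _as_user_table(self.user_ids, self.values, self.goal_ids, "scores")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.goal_ids))
        df.insert(0, "user_id", list(self.user_ids))
        return df


def compute_quality_scores(responses: ResponseMatrix, schema: FFQSchema) -> QualityScores:
    """Score each goal as the sum of its contributing questions' portions/day.

    The sum keeps scores on the same portions-per-day scale as the answers,
    so goal thresholds and prediction errors stay directly interpretable.
    Linear in the responses, with no cross-user coupling.
    """
    if responses.question_ids != schema.question_ids:
        raise ValueError("responses do not match schema question ids/order")
    values = responses.values @ schema.mapping_matrix().T
    return QualityScores(responses.user_ids, schema.goal_ids, values)


# --- serialisation -----------------------------------------------------------

_DIRECTION_TOKENS = {d.value: d for d in Direction}


def _parse_goal(raw: dict) -> Goal:
    try:
        direction = _DIRECTION_TOKENS[str(raw.get("direction", "")).lower()]
    except KeyError:
        raise SchemaError(
            f"goal {raw.get('id')!r}: direction must be one of "
            f"{sorted(_DIRECTION_TOKENS)}, got {raw.get('direction')!r}"
        ) from None
    try:
        threshold = float(raw["threshold"])
    except (KeyError, TypeError, ValueError):
        raise SchemaError(f"goal {raw.get('id')!r}: bad or missing threshold") from None
    return Goal(
        id=str(raw["id"]),
        label=str(raw.get("label", raw["id"])),
        threshold=threshold,
        direction=direction,
        questions=tuple(raw.get("questions", ())),
    )


def schema_from_dict(raw: dict) -> FFQSchema:
    """Build and validate a schema from a plain dict (parsed JSON/YAML)."""
    try:
        questions = tuple(
            Question(
                id=str(q["id"]),
                label=str(q.get("label", q["id"])),
                portion_unit=str(q.get("portion_unit", "portions/day")),
            )
            for q in raw["questions"]
        )
        goal_dicts = list(raw["goals"])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"schema file: missing/invalid section ({exc})") from None
    goals = tuple(_parse_goal(g) for g in goal_dicts)
    return FFQSchema(questions=questions, goals=goals)


def schema_to_dict(schema: FFQSchema) -> dict:
    return {
        "questions": [
            {"id": q.id, "label": q.label, "portion_unit": q.portion_unit}
            for q in schema.questions
        ],
        "goals": [
            {
                "id": g.id,
                "label": g.label,
                "threshold": g.threshold,
                "direction": g.direction.value,
                "questions": list(g.questions),
            }
            for g in schema.goals
        ],
    }


def load_schema(path: str | Path) -> FFQSchema:
    """Load a schema from a JSON or YAML file and validate all invariants."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: not a mapping")
    return schema_from_dict(raw)


def save_schema(schema: FFQSchema, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schema_to_dict(schema), fh, sort_keys=False)


# --- default instrument ------------------------------------------------------

_QUESTIONS = [
    ("bread", "Bread"),
    ("pasta", "Pasta"),
    ("breakfast_cereals", "Breakfast cereals"),
    ("baked_sweets", "Baked sweets"),
    ("potatoes", "Potatoes"),
    ("fruit", "Fruit"),
    ("vegetables", "Vegetables"),
    ("red_meat", "Red meat"),
    ("white_meat", "White meat"),
    ("fish", "Fish"),
    ("conserved_fish", "Conserved fish"),
    ("eggs", "Eggs"),
    ("lentils", "Lentils"),
    ("milk_yoghurt", "Milk / yoghurt"),
    ("cheese", "Cheese"),
    ("olive_oil", "Olive oil"),
    ("other_oils_butter", "Other oils / butter"),
    ("dried_fruit", "Dried fruit"),
    ("water", "Water"),
    ("processed_meat", "Processed meat"),
    ("sweets_snacks", "Sweets / snacks"),
    ("sugar", "Sugar"),
    ("honey_marmalade", "Honey / marmalade"),
    ("sweet_drinks", "Sweet drinks"),
]

# Default goal table.  The mapping, directions and thresholds are an editable
# convention shipped with the package, not measured values: thresholds in
# particular are placeholders on the portions/day scale and should be replaced
# with dietary-guideline values for any real deployment (see docs/methods.md).
# "other_oils_butter" contributes to no goal (its healthy direction is
# ambiguous).
_GOALS = [
    ("fruit_and_vegetables", "Fruit & vegetables", 5.0, Direction.AT_LEAST,
     ("fruit", "vegetables")),
    ("carbohydrates", "Carbohydrates", 4.0, Direction.AT_MOST,
     ("bread", "pasta", "breakfast_cereals", "potatoes")),
    ("proteins", "Proteins", 2.0, Direction.AT_MOST,
     ("red_meat", "white_meat", "fish", "conserved_fish", "eggs", "lentils")),
    ("milk", "Milk", 2.0, Direction.AT_MOST, ("milk_yoghurt", "cheese")),
    ("oil", "Oil", 2.0, Direction.AT_LEAST, ("olive_oil",)),
    ("water", "Water", 6.0, Direction.AT_LEAST, ("water",)),
    ("dried_fruit", "Dried fruit", 1.0, Direction.AT_LEAST, ("dried_fruit",)),
    ("processed_meats", "Processed meats", 0.5, Direction.AT_MOST,
     ("processed_meat",)),
    ("sweets_snacks", "Sweets / snacks", 1.0, Direction.AT_MOST,
     ("baked_sweets", "sweets_snacks")),
    ("sweet_drinks", "Sweet drinks", 0.5, Direction.AT_MOST, ("sweet_drinks",)),
    ("sugar", "Sugar", 2.0, Direction.AT_MOST, ("sugar", "honey_marmalade")),
]


def default_schema() -> FFQSchema:
    """The bundled 24-question / 11-goal Mediterranean-diet instrument."""
    return FFQSchema(
        questions=tuple(Question(id=i, label=l) for i, l in _QUESTIONS),
        goals=tuple(
            Goal(id=i, label=l, threshold=t, direction=d, questions=q)
            for i, l, t, d, q in _GOALS
        ),
    )
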