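"""Synthetic FFQ populations.

The reference dataset behind this kind of study is typically not
redistributable, so the package ships a seeded generator that emulates its
relevant structure: non-negative portions-per-day answers, correlation within
food groups (which is what makes feature selection non-trivial), and
heterogeneous goal attainment across users (which is what gives the
personalised selection arm signal to exploit).

Each user is drawn from a mixture of diet profiles.  A profile fixes the mean
portions/day and a coefficient of variation per question; answers are drawn
from a multivariate normal with block-structured correlation and truncated at
zero.  Truncation (rather than resampling) is simple and monotone; it biases
means upward slightly for questions whose mean is small relative to their
standard deviation — see docs/methods.md.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .schema import FFQSchema, ResponseMatrix, default_schema

__all__ = [
    "DietProfile",
    "CorrelationBlock",
    "PopulationSpec",
    "simulate_responses",
    "default_population",
    "load_population",
    "save_population",
]


@dataclass(frozen=True)
class DietProfile:
    """Per-question mean portions/day and coefficient of variation."""

    name: str
    mean_portions: np.ndarray
    dispersion: np.ndarray  # coefficient of variation, > 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_portions",
                           np.asarray(self.mean_portions, dtype=float))
        object.__setattr__(self, "dispersion",
                           np.asarray(self.dispersion, dtype=float))
        if np.any(self.mean_portions < 0):
            raise ValueError(f"profile {self.name!r}: means must be >= 0")
        if np.any(self.dispersion <= 0):
            raise ValueError(f"profile {self.name!r}: dispersion must be > 0")
        if self.mean_portions.shape != self.dispersion.shape:
            raise ValueError(f"profile {self.name!r}: shape mismatch")


@dataclass(frozen=True)
class CorrelationBlock:
    """A group of question ids sharing a common within-block correlation."""

    question_ids: tuple[str, ...]
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"block {self.question_ids}: rho must be in [0, 1)")


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture of diet profiles plus correlation structure and a seed."""

    profiles: tuple[DietProfile, ...]
    weights: tuple[float, ...]
    correlation_blocks: tuple[CorrelationBlock, ...]
    n_users: int
    seed: int

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("population: at least one profile required")
        if len(self.weights) != len(self.profiles):
            raise ValueError("population: one mixture weight per profile")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("population: weights must be >= 0 and sum to 1")
        if self.n_users <= 0:
            raise ValueError("population: n_users must be positive")
        seen: set[str] = set()
        for block in self.correlation_blocks:
            overlap = seen.intersection(block.question_ids)
            if overlap:
                raise ValueError(f"population: overlapping blocks at {sorted(overlap)}")
            seen.update(block.question_ids)


def _correlation_matrix(spec: PopulationSpec, schema: FFQSchema) -> np.ndarray:
    corr = np.eye(schema.n_questions)
    for block in spec.correlation_blocks:
        idx = [schema.question_index(q) for q in block.question_ids]
        for i in idx:
            for j in idx:
                if i != j:
                    corr[i, j] = block.rho
    return corr


def simulate_responses(spec: PopulationSpec, schema: FFQSchema) -> ResponseMatrix:
    """Draw a users x questions portions/day matrix; identical per (spec, seed)."""
    p = schema.n_questions
    for profile in spec.profiles:
        if profile.mean_portions.shape != (p,):
            raise ValueError(
                f"profile {profile.name!r}: expected {p} questions, "
                f"got {profile.mean_portions.shape}"
            )
    rng = np.random.default_rng(spec.seed)
    corr = _correlation_matrix(spec, schema)
    chol = np.linalg.cholesky(corr)

    component = rng.choice(
        len(spec.profiles), size=spec.n_users, p=np.asarray(spec.weights, dtype=float)
    )
    z = rng.standard_normal((spec.n_users, p)) @ chol.T
    means = np.stack([pr.mean_portions for pr in spec.profiles])[component]
    sds = np.stack(
        [pr.mean_portions * pr.dispersion for pr in spec.profiles]
    )[component]
    values = np.maximum(means + sds * z, 0.0)
    user_ids = tuple(f"u{i:05d}" for i in range(spec.n_users))
    return ResponseMatrix(user_ids, schema.question_ids, values)


# Default mixture: three diet profiles that violate different subsets of the
# default thresholds.  "prudent" satisfies every default threshold at its
# mean; "sweet_tooth" strongly over-reaches sugar, sweets/snacks and sweet
# drinks; "low_veg" under-reaches the at-least goals (fruit & vegetables,
# water, dried fruit, oil).  Means are portions/day; question order matches
# the default schema.
_PROFILE_MEANS = {
    "prudent": {
        "bread": 1.5, "pasta": 1.0, "breakfast_cereals": 0.5, "baked_sweets": 0.3,
        "potatoes": 0.8, "fruit": 2.5, "vegetables": 3.0, "red_meat": 0.3,
        "white_meat": 0.4, "fish": 0.4, "conserved_fish": 0.1, "eggs": 0.3,
        "lentils": 0.4, "milk_yoghurt": 1.0, "cheese": 0.8, "olive_oil": 2.5,
        "other_oils_butter": 0.3, "dried_fruit": 1.3, "water": 7.0,
        "processed_meat": 0.3, "sweets_snacks": 0.4, "sugar": 1.0,
        "honey_marmalade": 0.5, "sweet_drinks": 0.2,
    },
    "sweet_tooth": {
        "bread": 2.0, "pasta": 1.2, "breakfast_cereals": 1.0, "baked_sweets": 1.4,
        "potatoes": 1.0, "fruit": 1.8, "vegetables": 2.0, "red_meat": 0.5,
        "white_meat": 0.4, "fish": 0.2, "conserved_fish": 0.1, "eggs": 0.3,
        "lentils": 0.2, "milk_yoghurt": 1.2, "cheese": 1.0, "olive_oil": 1.5,
        "other_oils_butter": 0.6, "dried_fruit": 0.4, "water": 4.0,
        "processed_meat": 0.6, "sweets_snacks": 1.6, "sugar": 3.5,
        "honey_marmalade": 1.5, "sweet_drinks": 1.5,
    },
    "low_veg": {
        "bread": 1.8, "pasta": 1.5, "breakfast_cereals": 0.8, "baked_sweets": 0.6,
        "potatoes": 1.2, "fruit": 0.8, "vegetables": 1.0, "red_meat": 0.8,
        "white_meat": 0.6, "fish": 0.2, "conserved_fish": 0.2, "eggs": 0.4,
        "lentils": 0.1, "milk_yoghurt": 0.8, "cheese": 1.2, "olive_oil": 1.0,
        "other_oils_butter": 0.8, "dried_fruit": 0.2, "water": 3.0,
        "processed_meat": 0.8, "sweets_snacks": 0.8, "sugar": 1.8,
        "honey_marmalade": 0.4, "sweet_drinks": 0.8,
    },
}
_PROFILE_WEIGHTS = {"prudent": 0.40, "sweet_tooth": 0.35, "low_veg": 0.25}
_DEFAULT_CV = 0.4
_DEFAULT_BLOCKS = (
    CorrelationBlock(("bread", "pasta", "breakfast_cereals", "potatoes"), 0.6),
    CorrelationBlock(
        ("baked_sweets", "sweets_snacks", "sugar", "honey_marmalade", "sweet_drinks"),
        0.5,
    ),
    CorrelationBlock(("fruit", "vegetables"), 0.5),
)


def default_population(
    n_users: int, seed: int, schema: FFQSchema | None = None
) -> PopulationSpec:
    """Three-profile mixture with heterogeneous goal attainment.

    The prudent profile meets every default threshold at its mean vector, the
    sweet-tooth profile strongly violates the sugar-related at-most goals, and
    the low-veg profile under-reaches the at-least goals; the carbohydrate and
    sweets food groups each form a correlation block.
    """
    schema = schema or default_schema()
    profiles = []
    for name in ("prudent", "sweet_tooth", "low_veg"):
        means = np.array([_PROFILE_MEANS[name][q] for q in schema.question_ids])
        profiles.append(
            DietProfile(name, means, np.full(schema.n_questions, _DEFAULT_CV))
        )
    return PopulationSpec(
        profiles=tuple(profiles),
        weights=tuple(_PROFILE_WEIGHTS[p.name] for p in profiles),
        correlation_blocks=_DEFAULT_BLOCKS,
        n_users=n_users,
        seed=seed,
    )


# --- serialisation -----------------------------------------------------------

def population_to_dict(spec: PopulationSpec, schema: FFQSchema) -> dict:
    return {
        "n_users": spec.n_users,
        "seed": spec.seed,
        "profiles": [
            {
                "name": pr.name,
                "weight": float(w),
                "mean_portions": {
                    q: float(m) for q, m in zip(schema.question_ids, pr.mean_portions)
                },
                "dispersion": {
                    q: float(d) for q, d in zip(schema.question_ids, pr.dispersion)
                },
            }
            for pr, w in zip(spec.profiles, spec.weights)
        ],
        "correlation_blocks": [
            {"questions": list(b.question_ids), "rho": b.rho}
            for b in spec.correlation_blocks
        ],
    }


def population_from_dict(raw: dict, schema: FFQSchema) -> PopulationSpec:
    profiles = []
    weights = []
    for pr in raw["profiles"]:
        means = np.array([pr["mean_portions"][q] for q in schema.question_ids])
        disp = pr.get("dispersion", _DEFAULT_CV)
        if isinstance(disp, dict):
            disp = np.array([disp[q] for q in schema.question_ids])
        else:
            disp = np.full(schema.n_questions, float(disp))
        profiles.append(DietProfile(pr["name"], means, disp))
        weights.append(float(pr["weight"]))
    blocks = tuple(
        CorrelationBlock(tuple(b["questions"]), float(b["rho"]))
        for b in raw.get("correlation_blocks", ())
    )
    return PopulationSpec(
        tuple(profiles), tuple(weights), blocks,
        int(raw["n_users"]), int(raw["seed"]),
    )


def save_population(spec: PopulationSpec, path: str | Path,
                    schema: FFQSchema | None = None) -> None:
    schema = schema or default_schema()
    with open(path, "w") as fh:
        yaml.safe_dump(population_to_dict(spec, schema), fh, sort_keys=False)


def load_population(path: str | Path, schema: FFQSchema | None = None) -> PopulationSpec:
    schema = schema or default_schema()
    with open(path) as fh:
        return population_from_dict(yaml.safe_load(fh), schema)
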