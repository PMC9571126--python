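"""Experiment driver: enumeration, arm equivalences, sweep bookkeeping."""
import itertools

import numpy as np
import pandas as pd
import pytest

from ffqreduce import (
    ExperimentConfig,
    aggregate_by_active_count,
    default_population,
    enumerate_goal_combinations,
    prepare_seed_data,
    run_arm,
    run_sweep,
    sample_goal_combinations,
    simulate_responses,
)
from ffqreduce.schema import (
    Direction,
    FFQSchema,
    Goal,
    Question,
    ResponseMatrix,
)


class TestEnumeration:
    def test_three_goals_min_two(self):
        combos = enumerate_goal_combinations(("a", "b", "c"), min_active=2)
        assert combos == [("a", "b"), ("a", "c"), ("b", "c"), ("a", "b", "c")]

    def test_eleven_goals_min_two_count(self):
        combos = enumerate_goal_combinations(11, min_active=2)
        assert len(combos) == 2036  # 2^11 - 1 - 11
        brute = [
            c
            for size in range(12)
            for c in itertools.combinations(range(11), size)
            if size >= 2
        ]
        assert set(combos) == set(brute)

    def test_full_set_only(self):
        assert len(enumerate_goal_combinations(11, min_active=11)) == 1

    def test_bad_bounds_rejected(self):
        for bad in (0, 12):
            with pytest.raises(ValueError):
                enumerate_goal_combinations(11, min_active=bad)


class TestSampling:
    def test_stratified_sample_covers_sizes(self, schema):
        combos = sample_goal_combinations(schema.goal_ids, 20, seed=0)
        sizes = sorted({len(c) for c in combos})
        assert sizes == list(range(2, 12))
        assert len(combos) == 20
        assert len(set(combos)) == 20

    def test_requesting_more_than_exist_returns_all(self):
        combos = sample_goal_combinations(("a", "b", "c"), 100, seed=0)
        assert len(combos) == 4

    def test_deterministic_per_seed(self, schema):
        a = sample_goal_combinations(schema.goal_ids, 15, seed=3)
        b = sample_goal_combinations(schema.goal_ids, 15, seed=3)
        assert a == b


@pytest.fixture(scope="module")
def seed_data(schema):
    config = ExperimentConfig(seeds=(0,), n_users=400)
    responses = simulate_responses(default_population(400, 99), schema)
    return prepare_seed_data(responses, schema, 0, config), config


class TestRunArm:
    def test_all_arms_identical_at_full_questionnaire(self, schema, seed_data):
        data, config = seed_data
        active = ("sugar", "water", "proteins")
        errors = {
            arm: run_arm(arm, 24, active, data, config).errors
            for arm in ("random", "static", "personalised")
        }
        np.testing.assert_allclose(errors["random"], errors["static"], atol=1e-12)
        np.testing.assert_allclose(errors["static"], errors["personalised"],
                                   atol=1e-12)

    def test_planted_target_reaches_zero_error(self, schema, seed_data, rng):
        """A goal equal to a single question is predicted exactly once its
        question is selected."""
        questions = tuple(Question(f"q{j}", f"q{j}") for j in range(8))
        goals = tuple(
            Goal(f"g{j}", f"g{j}", 1.0, Direction.AT_MOST, (f"q{j}",))
            for j in range(3)
        )
        small = FFQSchema(questions, goals)
        values = rng.uniform(0, 4, size=(120, 8))
        responses = ResponseMatrix(
            tuple(f"u{i}" for i in range(120)), small.question_ids, values
        )
        config = ExperimentConfig(seeds=(1,), n_users=120)
        data = prepare_seed_data(responses, small, 1, config)
        res = run_arm("static", 3, ("g0", "g1", "g2"), data, config)
        assert np.all(res.errors < 1e-6)
        assert set(res.subset.question_ids) == {"q0", "q1", "q2"}

    def test_personalised_equals_static_with_uniform_weights(self, schema):
        from dataclasses import replace

        spec = default_population(400, 17)
        prudent = replace(spec, profiles=spec.profiles[:1], weights=(1.0,))
        responses = simulate_responses(prudent, schema)
        config = ExperimentConfig(seeds=(4,), n_users=400)
        data = prepare_seed_data(responses, schema, 4, config)
        active = ("proteins", "sugar", "milk")
        static = run_arm("static", 6, active, data, config)
        pers = run_arm("personalised", 6, active, data, config)
        np.testing.assert_array_equal(pers.weights, np.ones(3))
        np.testing.assert_allclose(pers.errors, static.errors, atol=1e-12)

    def test_unknown_arm_rejected(self, schema, seed_data):
        data, config = seed_data
        with pytest.raises(ValueError):
            run_arm("greedy", 4, ("sugar", "water"), data, config)


class TestRunSweep:
    def test_record_bookkeeping_single_cell(self, schema):
        config = ExperimentConfig(
            arms=("static",), feature_counts=(6,),
            combinations=(("sugar", "water", "oil"),),
            seeds=(0,), n_users=200,
        )
        result = run_sweep(config, schema)
        assert len(result.records) == 3  # one record per activated goal
        assert result.n_failures == 0
        assert set(result.records["goal"]) == {"sugar", "water", "oil"}

    def test_record_cardinality_full_factorial(self, schema):
        combos = (("sugar", "water"), ("oil", "milk", "proteins"))
        config = ExperimentConfig(
            arms=("random", "static"), feature_counts=(4, 12),
            combinations=combos, seeds=(0, 1), n_users=200,
        )
        result = run_sweep(config, schema)
        expected = 2 * 2 * 2 * sum(len(c) for c in combos)
        assert len(result.records) == expected
        assert result.n_failures == 0

    def test_rerun_reproduces_records_exactly(self, schema):
        config = ExperimentConfig(
            feature_counts=(4,), n_combinations=3, seeds=(2,), n_users=200
        )
        a = run_sweep(config, schema)
        b = run_sweep(config, schema)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_errors_non_negative(self, schema):
        config = ExperimentConfig(
            feature_counts=(6,), n_combinations=4, seeds=(0,), n_users=200
        )
        result = run_sweep(config, schema)
        assert (result.records["error"] >= 0).all()


class TestAggregate:
    def test_single_record_identity(self):
        df = pd.DataFrame(
            [dict(arm="static", n_features=4, active_set="a+b", n_active=2,
                  seed=0, goal="a", error=0.25, weight=np.nan, status="ok")]
        )
        agg = aggregate_by_active_count(df)
        assert len(agg) == 1
        assert agg.loc[0, "error"] == pytest.approx(0.25)

    def test_arithmetic_mean_of_two(self):
        rows = [
            dict(arm="static", n_features=4, active_set="a+b", n_active=2,
                 seed=0, goal="a", error=e, weight=np.nan, status="ok")
            for e in (0.2, 0.4)
        ]
        agg = aggregate_by_active_count(pd.DataFrame(rows))
        assert agg.loc[0, "error"] == pytest.approx(0.3)

    def test_matches_groupby_loop_oracle(self, rng):
        rows = []
        for arm in ("random", "static"):
            for n in (4, 9):
                for size in (2, 3):
                    for _ in range(5):
                        rows.append(dict(
                            arm=arm, n_features=n, active_set="x", n_active=size,
                            seed=0, goal="g", error=float(rng.uniform()),
                            weight=np.nan, status="ok",
                        ))
        df = pd.DataFrame(rows)
        agg = aggregate_by_active_count(df)
        for _, row in agg.iterrows():
            manual = np.mean([
                r["error"] for r in rows
                if (r["arm"], r["n_features"], r["n_active"])
                == (row["arm"], row["n_features"], row["n_active"])
            ])
            assert row["error"] == pytest.approx(manual, abs=1e-12)

    def test_failed_cells_excluded_and_counted(self):
        df = pd.DataFrame([
            dict(arm="static", n_features=4, active_set="a+b", n_active=2,
                 seed=0, goal="a", error=0.2, weight=np.nan, status="ok"),
            dict(arm="static", n_features=4, active_set="a+b", n_active=2,
                 seed=1, goal="a", error=np.nan, weight=np.nan, status="failed"),
        ])
        agg = aggregate_by_active_count(df)
        assert agg.loc[0, "error"] == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_by_active_count(pd.DataFrame(columns=["status", "error"]))
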