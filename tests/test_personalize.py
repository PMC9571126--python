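"""Threshold-distance weighting and two-step personalised selection."""
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ffqreduce import (
    ExperimentConfig,
    ThresholdVector,
    default_population,
    distance_to_threshold,
    distances_to_weights,
    personalised_selection,
    prepare_seed_data,
    reweight_targets,
    run_arm,
    simulate_responses,
)


class TestDistanceToThreshold:
    @pytest.mark.parametrize(
        "y_pred, y_opt, y_adj, expected",
        [
            (0.7, 0.5, +1, 0.2),   # at-most, over-reached
            (0.7, 0.5, -1, 0.0),   # at-least, satisfied
            (0.3, 0.5, -1, 0.2),   # at-least, under-reached
            (0.3, 0.5, +1, 0.0),   # at-most, satisfied
            (0.5, 0.5, +1, 0.0),   # exactly on threshold
            (0.5, 0.5, -1, 0.0),
        ],
    )
    def test_formula(self, y_pred, y_opt, y_adj, expected):
        tv = ThresholdVector(("g",), np.array([y_opt]), np.array([y_adj]))
        dist = distance_to_threshold(np.array([y_pred]), tv)
        assert dist[0] == pytest.approx(expected, abs=1e-12)

    def test_translation_covariance(self):
        """Pushing a violated goal delta further raises its distance by delta."""
        tv = ThresholdVector(("a", "b"), np.array([0.5, 0.5]),
                             np.array([1.0, -1.0]))
        base = distance_to_threshold(np.array([0.7, 0.3]), tv)
        delta = 0.11
        shifted = distance_to_threshold(np.array([0.7 + delta, 0.3 - delta]), tv)
        np.testing.assert_allclose(shifted - base, [delta, delta], atol=1e-12)

    def test_length_mismatch_rejected(self):
        tv = ThresholdVector(("a",), np.array([0.5]), np.array([1.0]))
        with pytest.raises(ValueError):
            distance_to_threshold(np.array([0.1, 0.2]), tv)

    def test_bad_adjustment_sign_rejected(self):
        with pytest.raises(ValueError):
            ThresholdVector(("a",), np.array([0.5]), np.array([0.0]))


class TestDistancesToWeights:
    def test_divide_by_max_with_floor(self):
        w = distances_to_weights(np.array([0.2, 0.1, 0.0]), floor=0.05)
        np.testing.assert_allclose(w, [1.0, 0.5, 0.05])

    def test_no_violation_gives_uniform_weights(self):
        np.testing.assert_array_equal(
            distances_to_weights(np.zeros(3)), np.ones(3)
        )

    def test_singleton(self):
        np.testing.assert_allclose(distances_to_weights(np.array([0.4])), [1.0])

    def test_minmax_variant_pins_least_violated_to_floor(self):
        w = distances_to_weights(
            np.array([0.3, 0.2, 0.1]), floor=0.05, scaling="minmax"
        )
        np.testing.assert_allclose(w, [1.0, 0.5, 0.05])

    @given(
        scale=st.floats(0.01, 100.0),
        seed=st.integers(0, 2**16),
    )
    def test_scale_invariance(self, scale, seed):
        dist = np.random.default_rng(seed).uniform(0, 1, size=5)
        np.testing.assert_allclose(
            distances_to_weights(dist * scale),
            distances_to_weights(dist),
            atol=1e-12,
        )

    def test_monotone_in_own_violation_when_maximal(self):
        base = distances_to_weights(np.array([0.4, 0.2]))
        more = distances_to_weights(np.array([0.6, 0.2]))
        assert more[0] >= base[0]
        assert more[1] <= base[1]  # relative weight of the other goal drops

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distances_to_weights(np.array([-0.1, 0.2]))


class TestReweightTargets:
    def test_identity_weights(self, rng):
        Y = rng.uniform(size=(10, 3))
        np.testing.assert_array_equal(reweight_targets(Y, np.ones(3)), Y)

    def test_column_scaling(self, rng):
        Y = rng.uniform(size=(10, 2))
        out = reweight_targets(Y, np.array([1.0, 0.5]))
        np.testing.assert_allclose(out[:, 0], Y[:, 0])
        np.testing.assert_allclose(out[:, 1], Y[:, 1] * 0.5)

    def test_matches_loop_oracle(self, rng):
        Y = rng.uniform(size=(6, 4))
        w = rng.uniform(0.1, 1.0, size=4)
        out = reweight_targets(Y, w)
        for u in range(6):
            for t in range(4):
                assert out[u, t] == pytest.approx(Y[u, t] * w[t], abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            reweight_targets(rng.uniform(size=(5, 3)), np.ones(2))


def _seed_data(spec, schema, seed=0, config=None):
    config = config or ExperimentConfig(seeds=(seed,))
    responses = simulate_responses(spec, schema)
    return prepare_seed_data(responses, schema, seed, config)


class TestPersonalisedSelection:
    def _run(self, schema, data, active, n, **kwargs):
        idx = schema.goal_indices(active)
        return personalised_selection(
            data.X_train, data.Y_train[:, idx], data.X_test, schema,
            active, n, data.target_params.select(idx),
            fold_seed=data.subseeds["folds"], **kwargs,
        )

    def test_all_thresholds_met_reduces_to_static(self, schema):
        # prudent-only population meets every threshold at its mean, so the
        # predicted violation distances vanish and weights stay uniform
        spec = default_population(600, 5)
        prudent = replace(spec, profiles=spec.profiles[:1], weights=(1.0,))
        data = _seed_data(prudent, schema, seed=5)
        sel = self._run(schema, data, ("proteins", "milk", "sugar"), 6)
        np.testing.assert_array_equal(sel.weights, np.ones(3))
        assert sel.subset == sel.static_subset

    def test_single_goal_reduces_to_static(self, schema):
        data = _seed_data(default_population(600, 3), schema, seed=3)
        sel = self._run(schema, data, ("sugar",), 4)
        np.testing.assert_allclose(sel.weights, [1.0])
        assert sel.subset == sel.static_subset

    def test_dominant_violator_gets_weight_one_and_its_questions(self, schema):
        # sweet-tooth-dominated mixture: sugar is the most violated of the
        # activated goals, so it takes weight 1 and its contributing
        # questions are pulled into the 4-question grid
        spec = default_population(1200, 2)
        skew = replace(spec, weights=(0.05, 0.90, 0.05))
        data = _seed_data(skew, schema, seed=2)
        sel = self._run(schema, data, ("sugar", "water"), 4)
        sugar_pos = 0  # order of activated goals
        assert sel.weights[sugar_pos] == pytest.approx(1.0)
        assert sel.distances[sugar_pos] > 0
        for q in schema.goal("sugar").questions:
            assert q in sel.subset.question_ids

    def test_deterministic(self, schema):
        data = _seed_data(default_population(400, 1), schema, seed=1)
        a = self._run(schema, data, ("sugar", "water", "oil"), 6)
        b = self._run(schema, data, ("sugar", "water", "oil"), 6)
        assert a.subset == b.subset
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_user_mode_validates_index(self, schema):
        data = _seed_data(default_population(400, 1), schema, seed=1)
        idx = schema.goal_indices(("sugar", "water"))
        with pytest.raises(ValueError):
            personalised_selection(
                data.X_train, data.Y_train[:, idx], data.X_test, schema,
                ("sugar", "water"), 4, data.target_params.select(idx),
                mode="user", user_index=None,
            )


class TestEndToEndDirection:
    def test_personalised_improves_strongly_violated_goal(self, schema):
        """Averaged over seeds, the personalised arm's error on a strongly
        violated activated goal is no worse than the static arm's."""
        active = ("sugar", "fruit_and_vegetables", "proteins", "water")
        gaps = []
        for seed in range(20):
            config = ExperimentConfig(seeds=(seed,), n_users=400)
            spec = default_population(400, seed * 31 + 7)
            skew = replace(spec, weights=(0.05, 0.90, 0.05))
            data = _seed_data(skew, schema, seed=seed, config=config)
            static = run_arm("static", 6, active, data, config)
            pers = run_arm("personalised", 6, active, data, config)
            worst = int(np.argmax(pers.weights))
            gaps.append(static.errors[worst] - pers.errors[worst])
        assert np.mean(gaps) >= 0
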