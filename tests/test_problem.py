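"""Unit tests for the calibration-problem core: cost, weights, simulation,
penalties, CSV round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from essopt import (
    INFEASIBLE_COST,
    BoxBounds,
    DynamicModel,
    MeasurementSeries,
    ObjectiveDataset,
    OptimizationProblem,
    build_weights,
    evaluate_cost,
    simulate_observables,
)


def series(exp, obs, values, coords=None, weight=None):
    return MeasurementSeries(exp, obs, np.asarray(values, float),
                             coords=None if coords is None else np.asarray(coords, float),
                             weight=weight)


def brute_force_cost(dataset, predictions):
    """Independent triple-loop reference implementation of J."""
    total = 0.0
    for s in dataset.series:
        w = 1.0 if s.weight is None else s.weight
        y = predictions[s.key]
        for k in range(len(s.values)):
            total += w * (s.values[k] - y[k]) ** 2
    return total


class TestEvaluateCost:
    def test_perfect_fit_is_zero(self):
        ds = ObjectiveDataset([series("e1", "o1", [1.0, 2.0, 3.0], [0, 1, 2], weight=2.0)])
        assert evaluate_cost(ds, {("e1", "o1"): np.array([1.0, 2.0, 3.0])}) == 0.0

    def test_single_residual(self):
        ds = ObjectiveDataset([series("e1", "o1", [1.0, 2.0], [0, 1], weight=1.0)])
        assert evaluate_cost(ds, {("e1", "o1"): np.array([0.0, 2.0])}) == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(25):
            ds = ObjectiveDataset([
                series(f"e{e}", f"o{o}", rng.normal(size=5), np.arange(5),
                       weight=float(rng.uniform(0.1, 3.0)))
                for e in range(3) for o in range(2)
            ])
            preds = {s.key: rng.normal(size=5) for s in ds.series}
            assert evaluate_cost(ds, preds) == pytest.approx(
                brute_force_cost(ds, preds), rel=1e-12)

    def test_nonfinite_prediction_is_infeasible(self):
        ds = ObjectiveDataset([series("e1", "o1", [1.0], None)])
        assert evaluate_cost(ds, {("e1", "o1"): np.array([np.nan])}) == INFEASIBLE_COST

    def test_misaligned_shapes_raise(self):
        ds = ObjectiveDataset([series("e1", "o1", [1.0, 2.0], [0, 1])])
        with pytest.raises(ValueError):
            evaluate_cost(ds, {("e1", "o1"): np.array([1.0])})
        with pytest.raises(ValueError):
            evaluate_cost(ds, {})

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=8))
    def test_cost_nonnegative(self, values):
        ds = ObjectiveDataset([series("e", "o", np.arange(1, len(values) + 1),
                                      np.arange(len(values)), weight=0.5)])
        assert evaluate_cost(ds, {("e", "o"): np.asarray(values)}) >= 0.0


class TestBuildWeights:
    def test_inverse_square_of_series_maximum(self):
        ds = build_weights(ObjectiveDataset([series("e", "o", [2.0, 4.0, -1.0], [0, 1, 2])]))
        assert ds.series[0].weight == pytest.approx(1.0 / 16.0)

    def test_all_zero_series_falls_back_to_one(self):
        ds = build_weights(ObjectiveDataset([series("e", "o", [0.0, 0.0], [0, 1])]))
        assert ds.series[0].weight == 1.0

    def test_user_weights_preserved(self):
        ds = build_weights(ObjectiveDataset([series("e", "o", [5.0], None, weight=7.0)]))
        assert ds.series[0].weight == 7.0

    def test_perfect_fit_stays_zero_after_weighting(self, rng):
        vals = rng.uniform(1, 10, size=6)
        ds = build_weights(ObjectiveDataset([series("e", "o", vals, np.arange(6))]))
        assert evaluate_cost(ds, {("e", "o"): vals.copy()}) == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            MeasurementSeries("e", "o", np.array([]))


def exp_decay_model():
    return DynamicModel(
        rhs=lambda x, p, t: -x,
        initial_state=np.array([1.0]),
        observation=lambda x, p, t: x,
        observables=["x"],
    )


class TestSimulateObservables:
    def test_exponential_decay_closed_form(self):
        ds = ObjectiveDataset([series("e", "x", [0.0], [1.0])])
        preds = simulate_observables(exp_decay_model(), np.zeros(1), ds)
        assert preds[("e", "x")][0] == pytest.approx(np.exp(-1.0), abs=1e-5)

    def test_observation_linearity(self):
        model = exp_decay_model()
        doubled = DynamicModel(
            rhs=model.rhs, initial_state=model.initial_state,
            observation=lambda x, p, t: 2 * x, observables=["x"],
        )
        ds = ObjectiveDataset([series("e", "x", [0.0, 0.0], [0.5, 1.0])])
        p1 = simulate_observables(model, np.zeros(1), ds)
        p2 = simulate_observables(doubled, np.zeros(1), ds)
        np.testing.assert_allclose(p2[("e", "x")], 2 * p1[("e", "x")], rtol=1e-9)

    def test_tolerance_self_consistency_two_state_mass_action(self):
        # dx1/dt = -k1 x1, dx2/dt = k1 x1 - k2 x2 at coarse vs 100x tighter tol
        def rhs(x, p, t):
            return np.array([-p[0] * x[0], p[0] * x[0] - p[1] * x[1]])

        p = np.array([1.3, 0.7])
        ds = ObjectiveDataset([series("e", "x2", np.zeros(5), np.linspace(0.5, 4.0, 5))])
        coarse = DynamicModel(rhs, np.array([1.0, 0.0]), lambda x, p, t: x,
                              ["x1", "x2"], rtol=1e-5, atol=1e-7)
        tight = DynamicModel(rhs, np.array([1.0, 0.0]), lambda x, p, t: x,
                             ["x1", "x2"], rtol=1e-7, atol=1e-9)
        yc = simulate_observables(coarse, p, ds)[("e", "x2")]
        yt = simulate_observables(tight, p, ds)[("e", "x2")]
        assert np.max(np.abs(yc - yt)) < 10 * 1e-5

    def test_integration_failure_returns_none(self):
        blowup = DynamicModel(
            rhs=lambda x, p, t: x * x * 1e8,
            initial_state=np.array([1.0]),
            observation=lambda x, p, t: x,
            observables=["x"],
            max_steps=50,
        )
        ds = ObjectiveDataset([series("e", "x", [0.0], [10.0])])
        assert simulate_observables(blowup, np.zeros(1), ds) is None

    def test_static_flag_bypasses_integration(self):
        model = DynamicModel(
            rhs=None, initial_state=np.zeros(0),
            observation=lambda x, p, t: np.array([p[0] ** 2]),
            observables=["y"], static=True,
        )
        ds = ObjectiveDataset([series("e", "y", [0.0])])
        preds = simulate_observables(model, np.array([3.0]), ds)
        assert preds[("e", "y")][0] == 9.0

    def test_deterministic_repeat(self):
        model = exp_decay_model()
        ds = ObjectiveDataset([series("e", "x", np.zeros(4), [0.5, 1.0, 2.0, 3.0])])
        a = simulate_observables(model, np.zeros(1), ds)[("e", "x")]
        b = simulate_observables(model, np.zeros(1), ds)[("e", "x")]
        np.testing.assert_array_equal(a, b)


class TestPenalizedObjective:
    def test_reduces_to_cost_without_constraints(self, quadratic_2d):
        assert quadratic_2d.evaluate(np.array([1.0, -2.0])) == 0.0

    def test_equality_penalty(self):
        prob = OptimizationProblem(
            lambda p: 1.0,
            BoxBounds(np.array([-1.0]), np.array([1.0])),
            penalty_weight=10.0,
            h_eq=lambda p: np.array([0.5]),
        )
        assert prob.evaluate(np.zeros(1)) == pytest.approx(1.0 + 2.5)

    def test_satisfied_inequality_adds_nothing(self):
        prob = OptimizationProblem(
            lambda p: 2.0,
            BoxBounds(np.array([-1.0]), np.array([1.0])),
            penalty_weight=10.0,
            h_in=lambda p: np.array([-3.0]),
        )
        assert prob.evaluate(np.zeros(1)) == 2.0

    def test_evaluation_counter_conservation(self, quadratic_2d, rng):
        pts = quadratic_2d.bounds.sample_uniform(rng, 37)
        for q in pts:
            quadratic_2d.evaluate(q)
        assert quadratic_2d.n_evals == 37


class TestDatasetCsv:
    def test_roundtrip(self, tmp_path, rng):
        ds = ObjectiveDataset([
            series("e1", "a", rng.normal(size=4), [0.0, 1.0, 2.5, 4.0]),
            series("e1", "flux", [1.5]),  # static
        ])
        path = tmp_path / "meas.csv"
        ds.to_csv(path)
        back = ObjectiveDataset.from_csv(path)
        assert len(back) == 2
        by_key = {s.key: s for s in back.series}
        np.testing.assert_allclose(by_key[("e1", "a")].values, ds.series[0].values)
        np.testing.assert_allclose(by_key[("e1", "a")].coords, ds.series[0].coords)
        assert by_key[("e1", "flux")].is_static

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("experiment_id,value\ne1,1.0\n")
        with pytest.raises(ValueError, match="observable_id"):
            ObjectiveDataset.from_csv(path)


class TestBoxBounds:
    def test_validation(self):
        with pytest.raises(ValueError):
            BoxBounds(np.array([0.0, 1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            BoxBounds(np.array([2.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            BoxBounds(np.array([np.inf]), np.array([1.0]))

    def test_clip_and_contains(self, rng):
        b = BoxBounds(np.array([-1.0, 0.0]), np.array([1.0, 2.0]))
        x = b.clip(np.array([5.0, -5.0]))
        np.testing.assert_array_equal(x, [1.0, 0.0])
        assert b.contains(x)
        assert not b.contains(np.array([1.5, 1.0]))
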