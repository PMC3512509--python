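"""Unit and property tests of the eSS building blocks and full runs."""

import numpy as np
import pytest

from essopt import BoxBounds, OptimizationProblem, Solution, ThreadSettings, ess_run
from essopt.ess import (
    RefSet,
    apply_stuck_policy,
    build_initial_refset,
    combine_member,
    generate_diverse_set,
    go_beyond,
    refset_dedup,
    select_local_start,
)
from conftest import BoundCheckingProblem


def sol(x, cost):
    return Solution(np.atleast_1d(np.asarray(x, float)), float(cost))


@pytest.fixture
def bounds2():
    return BoxBounds(np.array([-10.0, -10.0]), np.array([10.0, 10.0]))


class TestDiverseSet:
    def test_points_inside_box(self, bounds2, rng):
        pts = generate_diverse_set(bounds2, 50, rng)
        for p in pts:
            assert bounds2.contains(p)

    def test_latin_hypercube_stratification_1d(self, rng):
        bounds = BoxBounds(np.array([0.0]), np.array([10.0]))
        pts = generate_diverse_set(bounds, 10, rng)
        deciles = np.sort(np.floor(np.ravel(pts)).astype(int))
        np.testing.assert_array_equal(deciles, np.arange(10))

    def test_same_seed_identical(self, bounds2):
        a = generate_diverse_set(bounds2, 20, np.random.default_rng(7))
        b = generate_diverse_set(bounds2, 20, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_degenerate_coordinate_warned_and_fixed(self):
        bounds = BoxBounds(np.array([0.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.warns(UserWarning, match="degenerate"):
            pts = generate_diverse_set(bounds, 5, np.random.default_rng(0))
        assert np.all(pts[:, 1] == 2.0)


class TestInitialRefset:
    def test_quality_half_forced(self, rng):
        diverse = [sol([c], c) for c in [1, 2, 3, 4, 5, 6]]
        rs = build_initial_refset(diverse, 4, rng)
        costs = rs.costs
        assert 1.0 in costs and 2.0 in costs
        assert len(rs) == 4

    def test_sorted_ascending(self, rng):
        diverse = [sol([c], c) for c in rng.permutation(10)]
        rs = build_initial_refset(diverse, 5, rng)
        assert np.all(np.diff(rs.costs) >= 0)

    def test_reproducible_for_fixed_seed(self):
        diverse = [sol([c], c) for c in range(12)]
        a = build_initial_refset(diverse, 6, np.random.default_rng(3))
        b = build_initial_refset(diverse, 6, np.random.default_rng(3))
        assert [m.cost for m in a.members] == [m.cost for m in b.members]

    def test_too_few_points_is_structural_error(self, rng):
        with pytest.raises(ValueError, match="dim_refset"):
            build_initial_refset([sol([0], 0.0)], 3, rng)


def _eval_factory(bounds):
    counter = {"n": 0}

    def evaluate(x):
        counter["n"] += 1
        return Solution(np.array(x, float), float(np.sum(np.asarray(x) ** 2)), counter["n"])

    return evaluate, counter


class TestDedup:
    def test_identical_members_lower_ranked_replaced(self, bounds2, rng):
        evaluate, _ = _eval_factory(bounds2)
        rs = RefSet.from_members([sol([1.0, 1.0], 2.0), sol([1.0, 1.0], 2.0),
                                  sol([5.0, 5.0], 50.0)])
        refset_dedup(rs, bounds2, evaluate, 1e-3, rng)
        xs = np.array([m.x for m in rs.members])
        # exactly one of the two clones survives
        n_clones = sum(np.allclose(x, [1.0, 1.0]) for x in xs)
        assert n_clones == 1

    def test_distant_members_untouched(self, bounds2, rng):
        evaluate, counter = _eval_factory(bounds2)
        members = [sol([0.0, 0.0], 0.0), sol([1.0, 1.0], 2.0), sol([9.0, 9.0], 162.0)]
        rs = RefSet.from_members(members)
        refset_dedup(rs, bounds2, evaluate, 1e-3, rng)
        assert counter["n"] == 0
        assert [m.cost for m in rs.members] == [0.0, 2.0, 162.0]

    def test_zero_coordinate_uses_absolute_difference(self, bounds2, rng):
        evaluate, counter = _eval_factory(bounds2)
        # worse member x_j has a zero coordinate; |xi - xj| = 5e-4 <= eps -> duplicate
        rs = RefSet.from_members([sol([5e-4, 1.0], 1.0), sol([0.0, 1.0], 1.1)])
        refset_dedup(rs, bounds2, evaluate, 1e-3, rng)
        assert counter["n"] == 1  # replacement happened, no ZeroDivisionError


class TestCombine:
    def test_degenerate_box_returns_parent_point(self, bounds2, rng):
        evaluate, _ = _eval_factory(bounds2)
        rs = RefSet.from_members([sol([2.0, 2.0], 8.0), sol([2.0, 2.0], 8.0)])
        off = combine_member(rs, 0, rng, bounds2, evaluate)
        assert len(off) == 1
        np.testing.assert_allclose(off[0].x, [2.0, 2.0])

    def test_corner_arithmetic_1d(self, rng):
        bounds = BoxBounds(np.array([-10.0]), np.array([10.0]))
        evaluate, _ = _eval_factory(bounds)
        rs = RefSet.from_members([sol([0.0], 0.0), sol([2.0], 4.0)])
        for _ in range(50):
            (off,) = combine_member(rs, 0, rng, bounds, evaluate)
            assert -1.0 <= off.x[0] <= 1.0

    def test_clipping_to_bounds(self, rng):
        bounds = BoxBounds(np.array([0.0]), np.array([10.0]))
        evaluate, _ = _eval_factory(bounds)
        rs = RefSet.from_members([sol([0.0], 0.0), sol([2.0], 4.0)])
        for _ in range(50):
            (off,) = combine_member(rs, 0, rng, bounds, evaluate)
            assert 0.0 <= off.x[0] <= 1.0

    def test_offspring_count_is_b_minus_1(self, bounds2, rng):
        evaluate, _ = _eval_factory(bounds2)
        rs = RefSet.from_members([sol([i, i], 2 * i * i) for i in range(5)])
        assert len(combine_member(rs, 2, rng, bounds2, evaluate)) == 4


class TestGoBeyond:
    def test_worse_offspring_returns_parent(self, bounds2, rng):
        evaluate, counter = _eval_factory(bounds2)
        parent, off = sol([1.0, 0.0], 1.0), sol([2.0, 0.0], 4.0)
        rep, label = go_beyond(parent, off, evaluate, rng, bounds2)
        assert rep is parent and not label
        assert counter["n"] == 0

    def test_result_at_least_as_good_as_both(self, bounds2, rng):
        evaluate, _ = _eval_factory(bounds2)
        parent, off = sol([4.0, 0.0], 16.0), sol([2.0, 0.0], 4.0)
        rep, label = go_beyond(parent, off, evaluate, rng, bounds2)
        assert label
        assert rep.cost <= min(parent.cost, off.cost)

    def test_midpoint_hook_traces_hand_computed_path(self):
        # f(x) = x^2, parent at 4, offspring at 2; midpoint sampling gives
        # successive iterates 1, 0.25 (after lambda halves the box widens),
        # strictly decreasing in cost until the first non-improvement.
        bounds = BoxBounds(np.array([-10.0]), np.array([10.0]))
        calls = []

        def evaluate(x):
            calls.append(float(x[0]))
            return Solution(np.array(x, float), float(x[0] ** 2))

        def midpoint(lo, hi):
            return (lo + hi) / 2.0

        rep, label = go_beyond(sol([4.0], 16.0), sol([2.0], 4.0), evaluate,
                               np.random.default_rng(0), bounds, sampler=midpoint)
        assert label
        # first sample: box [2 - (4-2)/1, 2] = [0, 2] -> midpoint 1
        assert calls[0] == pytest.approx(1.0)
        costs = [c * c for c in calls]
        assert all(b < a for a, b in zip([4.0] + costs[:-1], costs)) or rep.cost <= 1.0
        assert rep.cost == min([4.0, 16.0] + costs)


class TestSelectLocalStart:
    def test_balance_zero_picks_best_cost(self):
        pool = [sol([0.0], 3.0), sol([1.0], 1.0), sol([2.0], 2.0)]
        z = select_local_start(pool, [sol([0.0], 0.0)], 0.0)
        assert z.cost == 1.0

    def test_empty_archive_picks_best_cost(self):
        pool = [sol([0.0], 3.0), sol([1.0], 1.0)]
        assert select_local_start(pool, [], 0.4).cost == 1.0

    def test_rank_combination_enumerated(self):
        # quality ranks (0,1,2) for costs (1,2,3); archive at x=0 gives
        # distances (3,1,2) -> diversity ranks (0,2,1); balance 0.5
        # scores: a: .5*0+.5*0=0 ... enumerate explicitly:
        pool = [sol([3.0], 1.0), sol([1.0], 2.0), sol([2.0], 3.0)]
        archive = [sol([0.0], 0.0)]
        # quality ranks: pool0=0, pool1=1, pool2=2
        # diversity (dist to archive): 3, 1, 2 -> ranks desc: pool0=0, pool2=1, pool1=2
        # scores @0.5: pool0=0, pool1=1.5, pool2=1.5 -> pool0 wins
        assert select_local_start(pool, archive, 0.5) is pool[0]

    def test_tie_broken_by_quality(self):
        pool = [sol([1.0], 1.0), sol([9.0], 2.0)]
        archive = [sol([0.0], 0.0)]
        # quality ranks (0,1); diversity ranks (1,0); scores @0.5: (0.5, 0.5)
        assert select_local_start(pool, archive, 0.5).cost == 1.0


class TestStuckPolicy:
    def test_labeled_members_replaced_and_reset(self, bounds2, rng):
        evaluate, _ = _eval_factory(bounds2)
        rs = RefSet.from_members([sol([1.0, 0.0], 1.0), sol([2.0, 0.0], 4.0)])
        rs.n_stuck = [5, 7]
        reps = [sol([0.5, 0.0], 0.25), sol([1.5, 0.0], 2.25)]
        apply_stuck_policy(rs, [True, True], reps, 20, bounds2, evaluate, rng)
        assert rs.n_stuck == [0, 0]
        assert sorted(m.cost for m in rs.members) == [0.25, 2.25]

    def test_stagnant_member_replaced_after_threshold(self, bounds2, rng):
        evaluate, counter = _eval_factory(bounds2)
        rs = RefSet.from_members([sol([1.0, 0.0], 1.0), sol([2.0, 0.0], 4.0)])
        nchange = 3
        for _ in range(nchange + 1):
            apply_stuck_policy(rs, [False, False], [None, None], nchange,
                               bounds2, evaluate, rng)
        assert counter["n"] == 2  # both members exceeded the threshold once


class TestEssRun:
    def test_constant_objective_terminates_at_budget(self):
        prob = OptimizationProblem(
            lambda p: 7.0, BoxBounds(np.array([-1.0, -1.0]), np.array([1.0, 1.0]))
        )
        best, state = ess_run(prob, ThreadSettings(rng_seed=0, max_evals=500,
                                                   local_solver="none"))
        assert best.cost == 7.0
        assert state.total_evals <= 500
        assert state.stop_reason == "max_evals"

    def test_fbest_trace_nonincreasing_and_feasible(self, rng):
        from essopt import benchmark_objective

        for seed in range(3):
            base = benchmark_objective("rastrigin", 4)
            prob = BoundCheckingProblem(base.objective, base.bounds)
            best, state = ess_run(prob, ThreadSettings(rng_seed=seed, max_evals=4000))
            fbests = [f for (_, _, f) in state.trace]
            assert all(b <= a for a, b in zip(fbests, fbests[1:]))
            assert prob.bounds.contains(best.x)
            assert state.total_evals == prob.n_evals

    def test_budget_conservation(self, quadratic_2d):
        best, state = ess_run(quadratic_2d, ThreadSettings(rng_seed=5, max_evals=2000))
        assert state.total_evals == quadratic_2d.n_evals
        assert state.total_evals <= 2000

    def test_seed_reproducibility(self):
        from essopt import benchmark_objective

        runs = []
        for _ in range(2):
            prob = benchmark_objective("ackley", 3)
            best, state = ess_run(prob, ThreadSettings(rng_seed=11, max_evals=3000))
            runs.append((best.cost, best.x.copy(), state.total_evals))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])
        assert runs[0][2] == runs[1][2]

    def test_initial_points_are_injected(self):
        # an initial point at the optimum must survive into the incumbent
        from essopt import benchmark_objective

        prob = benchmark_objective("sphere", 5)
        best, _ = ess_run(
            prob,
            ThreadSettings(rng_seed=2, max_evals=600, local_solver="none"),
            initial_points=[np.zeros(5)],
        )
        assert best.cost == 0.0

    def test_infeasible_settings_raise(self, quadratic_2d):
        with pytest.raises(ValueError, match="max_evals"):
            ess_run(quadratic_2d, ThreadSettings(max_evals=5, ndiverse=50))

    def test_rosenbrock_2d_regression(self):
        # seeded regression: eSS reliably solves 2-D Rosenbrock
        from essopt import benchmark_objective

        successes = 0
        for seed in range(5):
            prob = benchmark_objective("rosenbrock", 2)
            best, _ = ess_run(prob, ThreadSettings(rng_seed=seed, max_evals=50_000,
                                                   target_cost=1e-6))
            successes += best.cost < 1e-6
        assert successes >= 4
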