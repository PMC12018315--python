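"""Reward function, decision-space assembly and the particle swarm."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qsaropt.optimize import (ConstrainedObjective, DecisionSpace, RewardSpec,
                              assemble_decision_space, derive_ranges, pso_step,
                              reward, reward_batch, run_pso, SwarmState)
from qsaropt.selection import NormalizationParams


class TestReward:
    def test_optimal_combination_scores_five(self):
        assert reward((1, 1, 0, 1, 0)) == 5

    def test_worst_combination_scores_zero(self):
        assert reward((0, 0, 1, 0, 1)) == 0

    def test_matches_literal_formula_on_all_32_inputs(self):
        for g in itertools.product((0, 1), repeat=5):
            g1, g2, g3, g4, g5 = g
            assert reward(g) == g1 + g2 + (1 - g3) + g4 + (1 - g5)

    def test_exactly_16_of_32_feasible_at_threshold_3(self):
        feasible = sum(reward(g) >= 3 for g in itertools.product((0, 1), repeat=5))
        assert feasible == 16

    def test_flipping_toward_favorable_never_decreases(self):
        spec = RewardSpec()
        for g in itertools.product((0, 1), repeat=5):
            base = reward(g, spec)
            for i, fav in enumerate(spec.orientation):
                flipped = list(g)
                flipped[i] = fav
                assert reward(tuple(flipped), spec) >= base

    def test_batch_agrees_with_scalar(self, rng):
        L = rng.integers(0, 2, size=(40, 5))
        batch = reward_batch(L)
        assert all(batch[i] == reward(tuple(L[i])) for i in range(40))

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            reward((1, 1, 2, 0, 0))


class TestAssembly:
    def test_disjoint_lists(self):
        act = [f"a{i}" for i in range(20)]
        admet = {p: [f"{p}_{i}" for i in range(25)]
                 for p in ("Caco-2", "CYP3A4", "hERG", "HOB", "MN")}
        space = assemble_decision_space(act, admet)
        assert space.dim == 145 and space.duplicate_count == 0

    def test_five_identical_lists_plus_disjoint(self):
        shared = [f"s{i}" for i in range(25)]
        act = [f"a{i}" for i in range(20)]
        admet = {p: list(shared) for p in ("Caco-2", "CYP3A4", "hERG", "HOB", "MN")}
        space = assemble_decision_space(act, admet)
        assert space.dim == 45 and space.duplicate_count == 100

    def test_first_occurrence_order(self):
        space = assemble_decision_space(["b", "a"], {"MN": ["a", "c"]})
        assert space.names == ["b", "a", "c"]
        assert space.duplicate_count == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            assemble_decision_space([], {"MN": ["a"]})

    def test_bounds_source_attached(self):
        params = NormalizationParams(x_min=pd.Series({"a": -1.0, "b": 0.0}),
                                     x_max=pd.Series({"a": 3.0, "b": 10.0}))
        space = assemble_decision_space(["a"], {"MN": ["b"]}, bounds_source=params)
        assert np.allclose(space.denormalize(np.array([0.5, 0.1])), [1.0, 1.0])
        with pytest.raises(KeyError):
            assemble_decision_space(["zz"], {"MN": ["b"]}, bounds_source=params)


class _StubActivity:
    """Predicts the sum of its features."""

    def __init__(self, features):
        self.feature_list = features

    def predict(self, X):
        return np.atleast_2d(X).sum(axis=1)


class _StubAdmet:
    """Label 1 iff the mean of its features exceeds a cut."""

    def __init__(self, features, cut=0.0):
        self.feature_list = features
        self.cut = cut

    def predict_label(self, X):
        return (np.atleast_2d(X).mean(axis=1) >= self.cut).astype(int)


def _stub_objective(cut_herg=1.1, penalty=10.0):
    names = ["d0", "d1", "d2"]
    space = DecisionSpace(names=names, lower=np.zeros(3), upper=np.ones(3))
    activity = _StubActivity(["d0", "d1"])
    admet = {
        "Caco-2": _StubAdmet(["d0"]),            # always 1 (favorable)
        "CYP3A4": _StubAdmet(["d1"]),            # always 1 (favorable)
        "hERG": _StubAdmet(["d2"], cut=cut_herg),  # 0 unless d2 high (favorable=0)
        "HOB": _StubAdmet(["d0", "d2"]),         # always 1 (favorable)
        "MN": _StubAdmet(["d1"], cut=1.1),       # always 0 (favorable)
    }
    obj = ConstrainedObjective(space, activity, admet, penalty=penalty)
    return space, obj


class TestObjective:
    def test_feasible_point_has_zero_penalty(self):
        _, obj = _stub_objective()
        value, feasible, pic50, rew = obj(np.array([0.3, 0.4, 0.0]))
        assert feasible and rew == 5
        assert value == pytest.approx(-pic50) and pic50 == pytest.approx(0.7)

    def test_penalty_arithmetic(self):
        # force three unfavorable labels -> reward 2 -> shortfall 1 at threshold 3
        names = ["d0"]
        space = DecisionSpace(names=names, lower=np.zeros(1), upper=np.ones(1))
        activity = _StubActivity(["d0"])
        admet = {p: _StubAdmet(["d0"], cut=2.0) for p in
                 ("Caco-2", "CYP3A4", "hERG", "HOB", "MN")}  # all labels 0 -> reward 2
        obj = ConstrainedObjective(space, activity, admet, penalty=10.0)
        value, feasible, pic50, rew = obj(np.array([0.5]))
        assert rew == 2 and not feasible
        assert value == pytest.approx(-0.5 + 10.0)

    def test_unknown_feature_raises(self):
        space = DecisionSpace(names=["d0"], lower=np.zeros(1), upper=np.ones(1))
        with pytest.raises(KeyError):
            ConstrainedObjective(space, _StubActivity(["nope"]), {})


class TestPso:
    def test_stationary_when_no_attraction(self):
        space, obj = _stub_objective()
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(4, 3))
        vals, *_ = obj.evaluate(x)
        state = SwarmState(positions=x.copy(), velocities=np.zeros((4, 3)),
                           pbest_pos=x.copy(), pbest_val=vals.copy(),
                           gbest_pos=x[0].copy(), gbest_val=float(vals[0]),
                           w=0.8, c1=0.0, c2=0.0,
                           v_min=-np.full(3, 0.2), v_max=np.full(3, 0.2))
        # attraction terms vanish with c1 = c2 = 0 and zero velocity
        state.gbest_pos = x[int(np.argmin(vals))].copy()
        state.gbest_val = float(vals.min())
        new, _ = pso_step(state, obj, rng, space.lower, space.upper)
        assert np.array_equal(new.positions, x)

    def test_global_best_never_worsens(self):
        space, obj = _stub_objective()
        res = run_pso(space, obj, m=12, iters=25, seed=3)
        assert (np.diff(res.trace) <= 1e-12).all()

    def test_sphere_benchmark_2d_frozen(self):
        space = DecisionSpace(names=["x", "y"], lower=-np.ones(2), upper=np.ones(2))
        res = run_pso(space, lambda X: (X ** 2).sum(axis=1), m=20, iters=100, seed=0)
        assert res.best_value < 1e-8
        assert np.abs(res.best_position).max() < 1e-3

    def test_rosenbrock_benchmark_2d_frozen(self):
        space = DecisionSpace(names=["x", "y"], lower=np.full(2, -2.0),
                              upper=np.full(2, 2.0))
        rosen = lambda X: (1 - X[:, 0]) ** 2 + 100 * (X[:, 1] - X[:, 0] ** 2) ** 2
        res = run_pso(space, rosen, m=40, iters=300, seed=1)
        assert res.best_value < 1e-6
        assert np.allclose(res.best_position, [1.0, 1.0], atol=1e-2)

    def test_seeded_determinism(self):
        space, obj = _stub_objective()
        r1 = run_pso(space, obj, m=10, iters=15, seed=9)
        r2 = run_pso(space, obj, m=10, iters=15, seed=9)
        assert np.array_equal(r1.trace, r2.trace)
        assert np.array_equal(r1.best_position, r2.best_position)

    def test_invalid_sizes(self):
        space, obj = _stub_objective()
        with pytest.raises(ValueError):
            run_pso(space, obj, m=1, iters=5)
        with pytest.raises(ValueError):
            run_pso(space, obj, m=5, iters=0)


class TestDeriveRanges:
    def _result_with(self, positions, values, space):
        from qsaropt.optimize import OptimizationResult
        best = positions[0] if len(positions) else np.zeros(space.dim)
        return OptimizationResult(
            trace=np.array([0.0]), best_position=best,
            best_position_denorm=best,
            best_value=float(values.min()) if len(values) else 0.0,
            best_pic50=0.0, feasible_positions=positions,
            feasible_values=values, feasible_pic50=-values)

    def test_elementwise_min_max_hand_case(self):
        space = DecisionSpace(names=["a", "b"], lower=np.zeros(2), upper=np.ones(2))
        pts = np.array([[0.2, 0.4], [0.6, 0.1]])
        res = self._result_with(pts, np.array([-1.0, -2.0]), space)
        ranges = derive_ranges(res, space, top_fraction=1.0)
        assert ranges.loc[0, ["optimal_min", "optimal_max"]].tolist() == [0.2, 0.6]
        assert ranges.loc[1, ["optimal_min", "optimal_max"]].tolist() == [0.1, 0.4]

    def test_single_point_degenerate_range(self):
        space = DecisionSpace(names=["a"], lower=np.zeros(1), upper=np.ones(1))
        res = self._result_with(np.array([[0.37]]), np.array([-1.0]), space)
        ranges = derive_ranges(res, space, top_fraction=1.0)
        assert ranges.loc[0, "optimal_min"] == ranges.loc[0, "optimal_max"] == 0.37

    def test_top_fraction_filters_and_denormalizes(self):
        params_min = np.array([10.0])
        space = DecisionSpace(names=["a"], lower=np.zeros(1), upper=np.ones(1),
                              orig_min=params_min, orig_max=np.array([20.0]))
        pts = np.array([[0.0], [0.5], [1.0]])
        vals = np.array([-3.0, -2.0, -1.0])  # best point is 0.0
        res = self._result_with(pts, vals, space)
        ranges = derive_ranges(res, space, top_fraction=0.3)
        assert ranges.loc[0, "optimal_min"] == 10.0
        assert ranges.loc[0, "optimal_max"] == 10.0

    def test_no_feasible_point_raises(self):
        space = DecisionSpace(names=["a"], lower=np.zeros(1), upper=np.ones(1))
        res = self._result_with(np.empty((0, 1)), np.array([]), space)
        with pytest.raises(ValueError, match="feasible"):
            derive_ranges(res, space)
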