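"""Penalized-likelihood dating: objective, optimiser, cross-validation."""

import math

import numpy as np
import pytest

from chronoscreen.pl import (
    CalibrationConstraint,
    InfeasibleConstraintsError,
    PLProblem,
    SmoothingConfig,
    cross_validate_lambda,
    estimate_chronogram,
    pl_objective,
)
from chronoscreen.simulate import SimulationConfig, node_definitions, simulate_tree
from chronoscreen.trees import NodeQuery, read_tree
from oracles import grid_oracle, make_four_taxon_problem


def _two_tip_problem(x_a=10.0, root_age=2.0, L=1):
    tree = read_tree(f"(A:{x_a / L},B:0.0);", alignment_length=L)
    cons = [CalibrationConstraint(NodeQuery("A", "B"), root_age, root_age)]
    return PLProblem(tree, cons), tree


class TestObjective:
    def test_equal_rates_zero_out_the_penalty(self):
        """Under a strict clock the objective reduces to the Poisson term."""
        truth, obs = simulate_tree(SimulationConfig(n_tips=6, seed=0))
        defs = node_definitions(truth)
        cons = [CalibrationConstraint(defs["node1"], truth.root_age, truth.root_age)]
        prob = PLProblem(obs, cons)
        r = np.full(obs.tree.n_nodes, 3.0)
        ages = truth.ages
        t = prob.durations(ages)[1:]
        x = prob.x[1:]
        mu = 3.0 * t
        poisson = float(np.sum(np.where(x > 0, x * np.log(mu), 0.0) - mu))
        for lam in (0.0, 1.0, 1e4):
            assert pl_objective(prob, r, ages, lam) == pytest.approx(poisson)

    def test_single_branch_poisson_mle(self):
        """x=10 substitutions over duration 2 is maximised at rate 5."""
        prob, tree = _two_tip_problem(x_a=10.0, root_age=2.0)
        ages = np.array([2.0, 0.0, 0.0])
        grid = np.linspace(0.5, 20.0, 2000)
        a_idx = 1 if tree.tree.labels[1] == "A" else 2
        objs = []
        for rv in grid:
            r = np.zeros(3)
            r[a_idx] = rv
            r[3 - a_idx] = 1e-9
            objs.append(pl_objective(prob, r, ages, lam=0.0))
        assert grid[int(np.argmax(objs))] == pytest.approx(10.0 / 2.0, rel=0.01)

    def test_zero_duration_with_positive_count_is_minus_infinity(self):
        prob, tree = _two_tip_problem()
        ages = np.array([0.0, 0.0, 0.0])
        assert pl_objective(prob, np.ones(3), ages, 1.0) == -math.inf


class TestEstimateChronogram:
    def test_three_taxon_fit_matches_grid_search(self):
        """Joint optimiser lands on the exhaustive grid-search optimum."""
        tree = read_tree("((A:0.03,B:0.032):0.03,C:0.061);", alignment_length=2000)
        cons = [CalibrationConstraint(NodeQuery("A", "C"), 100.0, 100.0)]
        ages_o, obj_o = grid_oracle(tree, cons, lam=1.0)
        ch = estimate_chronogram(tree, cons, SmoothingConfig(seed=0, restarts=3))
        for i in tree.tree.internal:
            if ages_o[i] > 1e-6:
                assert ch.ages[i] == pytest.approx(ages_o[i], rel=5e-3)
        assert ch.metadata["objective"] == pytest.approx(obj_o, abs=1e-3 * abs(obj_o))

    def test_strict_clock_point_root_recovers_truth(self):
        """Noiseless clocklike data + point root calibration: exact ages."""
        cfg = SimulationConfig(n_tips=8, seed=7, alignment_length=math.inf)
        truth, obs = simulate_tree(cfg)
        defs = node_definitions(truth)
        cons = [CalibrationConstraint(defs["node1"], truth.root_age, truth.root_age)]
        ch = estimate_chronogram(obs, cons, SmoothingConfig(seed=1, restarts=2))
        for lab, q in defs.items():
            assert ch.age_of(q) == pytest.approx(truth.age_of(q), rel=0.01)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_constraints_hold_exactly_and_objective_improves(self, seed):
        truth, obs = simulate_tree(SimulationConfig(n_tips=10, seed=seed))
        defs = node_definitions(truth)
        deep = max(
            (lab for lab in defs if lab != "node1"),
            key=lambda l: truth.age_of(defs[l]),
        )
        lo, hi = 0.7 * truth.age_of(defs[deep]), 0.9 * truth.age_of(defs[deep])
        cons = [CalibrationConstraint(defs[deep], lo, hi)]
        ch = estimate_chronogram(obs, cons, SmoothingConfig(seed=seed, restarts=2))
        age = ch.age_of(defs[deep])
        assert lo <= age <= hi
        at = ch.tree
        assert np.all(ch.ages[at.parent[1:]] >= ch.ages[1:] - 1e-12)
        assert ch.metadata["objective"] >= ch.metadata["objective_init"]

    def test_large_lambda_forces_a_common_rate(self):
        """Clocklike data + heavy smoothing: fitted rates collapse."""
        cfg = SimulationConfig(n_tips=8, seed=5)  # strict clock, Poisson noise
        truth, obs = simulate_tree(cfg)
        defs = node_definitions(truth)
        cons = [CalibrationConstraint(defs["node1"], truth.root_age, truth.root_age)]
        ch = estimate_chronogram(obs, cons, SmoothingConfig(lam=1e6, seed=2, restarts=2))
        rates = ch.rates[1:]
        assert np.nanmax(rates) / np.nanmin(rates) < 1.01

    def test_infeasible_nesting_detected_before_optimisation(self):
        truth, obs = simulate_tree(SimulationConfig(n_tips=8, seed=1))
        defs = node_definitions(truth)
        deep = max(
            (lab for lab in defs if lab != "node1"),
            key=lambda l: truth.age_of(defs[l]),
        )
        cons = [
            CalibrationConstraint(defs[deep], 120.0, 150.0),  # child min 120
            CalibrationConstraint(defs["node1"], 50.0, 100.0),  # ancestor max 100
        ]
        with pytest.raises(InfeasibleConstraintsError):
            estimate_chronogram(obs, cons, SmoothingConfig())

    def test_min_only_calibrations_are_unidentifiable(self):
        truth, obs = simulate_tree(SimulationConfig(n_tips=6, seed=1))
        defs = node_definitions(truth)
        with pytest.raises(InfeasibleConstraintsError, match="identifiable"):
            estimate_chronogram(
                obs, [CalibrationConstraint(defs["node1"], 100.0)], SmoothingConfig()
            )

    def test_inverted_bounds_rejected_at_construction(self):
        with pytest.raises(InfeasibleConstraintsError):
            CalibrationConstraint(NodeQuery("A", "B"), 10.0, 5.0)

    def test_deterministic_given_seed(self):
        tree, cons, _ = make_four_taxon_problem(3)
        c1 = estimate_chronogram(tree, cons, SmoothingConfig(seed=9, restarts=2))
        c2 = estimate_chronogram(tree, cons, SmoothingConfig(seed=9, restarts=2))
        np.testing.assert_array_equal(c1.ages, c2.ages)
        np.testing.assert_array_equal(c1.rates[1:], c2.rates[1:])


class TestCrossValidation:
    def _clock_data(self, noiseless=True, seed=0):
        L = math.inf if noiseless else 1044
        cfg = SimulationConfig(n_tips=6, seed=seed, alignment_length=L)
        truth, obs = simulate_tree(cfg)
        defs = node_definitions(truth)
        cons = [CalibrationConstraint(defs["node1"], truth.root_age, truth.root_age)]
        return obs, cons

    def test_clocklike_data_ties_resolve_to_largest_lambda(self):
        obs, cons = self._clock_data(noiseless=True)
        grid = [0.1, 1.0, 10.0]
        best, table = cross_validate_lambda(obs, cons, grid, seed=0)
        scores = table["cv_score"].to_numpy()
        # under a true clock every lambda predicts the held-out branches
        # essentially perfectly: all scores sit below the Poisson noise
        # floor (non-increasing up to that floor) and the tie resolves
        # to the largest (smoothest) lambda
        assert all(s2 <= s1 + 1.0 for s1, s2 in zip(scores, scores[1:]))
        assert best == max(grid)

    def test_deterministic_selection(self):
        obs, cons = self._clock_data(noiseless=False, seed=4)
        grid = [0.1, 10.0]
        b1, t1 = cross_validate_lambda(obs, cons, grid, seed=11)
        b2, t2 = cross_validate_lambda(obs, cons, grid, seed=11)
        assert b1 == b2
        np.testing.assert_array_equal(t1["cv_score"], t2["cv_score"])

    def test_degenerate_grid_returns_it_with_note(self):
        obs, cons = self._clock_data()
        best, table = cross_validate_lambda(obs, cons, [2.5], seed=0)
        assert best == 2.5
        assert "note" in table.columns

    def test_two_rate_data_selects_finite_lambda(self):
        cfg = SimulationConfig(n_tips=6, seed=8, clock="lognormal", log_sd=0.6)
        truth, obs = simulate_tree(cfg)
        defs = node_definitions(truth)
        cons = [CalibrationConstraint(defs["node1"], truth.root_age, truth.root_age)]
        grid = [0.1, 1.0, 10.0]
        best, table = cross_validate_lambda(obs, cons, grid, seed=2)
        assert best in grid
        assert len(table) == len(grid)

    def test_empty_grid_rejected(self):
        obs, cons = self._clock_data()
        with pytest.raises(ValueError):
            cross_validate_lambda(obs, cons, [], seed=0)
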