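"""Prioritized optimizer: stage mechanics on hand-built tiny instances."""

import numpy as np
import pytest
from scipy import sparse

import prioplan as pp
from prioplan.influence import Plan
from prioplan.optimizer import _StageSolver, InfeasibleProblemError
from prioplan.wishlist import HardConstraint, Objective, UNIT_NONE

from helpers import tiny_problem


class TestGoalClamping:
    """An easily-met priority-1 goal is fixed at the goal, freeing room below."""

    def build(self):
        # beamlet 0 doses the OAR and the target equally; beamlet 1 only the
        # target: priority-1 (OAR mean, goal 12) is trivially met at x=0,
        # priority-2 (target mean, maximized by pushing toward its bound)
        # then needs the OAR headroom that clamping preserves.
        D = np.array([
            [1.0, 0.0],   # oar voxel, coupled to target via beamlet 0
            [1.0, 0.0],   # target voxel A
            [0.0, 1.0],   # target voxel B
        ])
        volumes = {
            "oar": [True, False, False],
            "target": [False, True, True],
        }
        constraints = [HardConstraint("patient", "max", 70.0)]
        objectives = [
            Objective(1, "oar", "mean", 12.0),
            Objective(2, "target", "ltcp", 1.0, UNIT_NONE, alpha=0.25),
        ]
        return tiny_problem(D, volumes, constraints, objectives)

    def test_fixed_constraint_equals_goal_not_optimum(self):
        dij, wl, ss = self.build()
        rx = pp.Prescription(60.0, 2.0, 30)
        plan, report = pp.prioritized_optimize(dij, wl, ss, rx)
        s1 = report.stage(1, phase=1)
        assert s1.clamped_at_goal
        assert s1.fixed_bound == 12.0
        assert s1.achieved <= 12.0 + 1e-6

    def test_lower_priority_exploits_the_freed_room(self):
        dij, wl, ss = self.build()
        rx = pp.Prescription(60.0, 2.0, 30)
        _, clamped = pp.prioritized_optimize(dij, wl, ss, rx)
        dij2, wl2, ss2 = self.build()
        _, unclamped = pp.prioritized_optimize(
            dij2, wl2, ss2, rx, pp.SolverOptions(clamp_at_goal=False))
        # lower LTCP = better coverage; clamping must help priority 2
        assert clamped.stage(2, 1).achieved < unclamped.stage(2, 1).achieved / 10


class TestEmptyAndDegenerate:
    def test_no_objectives_returns_feasible_plan(self):
        D = np.array([[1.0, 0.5], [0.2, 1.0]])
        dij, wl, ss = tiny_problem(
            D, {"v": [True, True]},
            [HardConstraint("v", "max", 50.0)], [])
        plan, report = pp.prioritized_optimize(dij, wl, ss, pp.Prescription(60.0, 2.0, 30))
        assert np.all(plan.dose <= 50.0 * 1.001)
        assert report.phase1() == []

    def test_empty_objective_volume_is_skipped(self):
        D = np.array([[1.0, 0.2], [0.3, 1.0], [0.5, 0.5]])
        dij, wl, ss = tiny_problem(
            D,
            {"t": [True, True, False], "void": [False, False, False]},
            [HardConstraint("patient", "max", 70.0)],
            [
                Objective(1, "t", "mean", 10.0),
                Objective(2, "void", "max", 40.0),
            ],
        )
        _, report = pp.prioritized_optimize(dij, wl, ss, pp.Prescription(60.0, 2.0, 30))
        assert report.stage(2, 1).status.startswith("skipped")
        assert report.stage(1, 1).status == "converged"


class TestDeterminism:
    def test_identical_inputs_identical_fluence_and_report(self):
        rng = np.random.default_rng(12)
        D = rng.uniform(0, 1, size=(20, 4))
        volumes = {"t": [True] * 7 + [False] * 13, "o": [False] * 7 + [True] * 13}
        constraints = [HardConstraint("patient", "max", 66.0)]
        objectives = [
            Objective(1, "t", "ltcp", 1.0, UNIT_NONE, alpha=0.3),
            Objective(2, "o", "mean", 5.0),
        ]
        results = []
        for _ in range(2):
            dij, wl, ss = tiny_problem(D, volumes, constraints, objectives)
            plan, report = pp.prioritized_optimize(
                dij, wl, ss, pp.Prescription(60.0, 2.0, 30))
            results.append((plan.fluence, [s.achieved for s in report.stages]))
        np.testing.assert_allclose(results[0][0], results[1][0], atol=1e-9)
        np.testing.assert_allclose(results[0][1], results[1][1], atol=1e-9)


class TestStageSolverInternals:
    def test_conflicting_rows_certify_infeasibility(self):
        # x <= 1 (max row) conflicts with x >= 3 encoded as -x <= -3
        G = sparse.csr_matrix(np.array([[1.0], [-1.0]]))
        h = np.array([1.0, -3.0])
        solver = _StageSolver(1, G, h, [], np.array([10.0]),
                              pp.SolverOptions())
        with pytest.raises(InfeasibleProblemError):
            solver.solve(("lin", np.ones(1)), np.zeros(1))


class TestHardConstraintChecks:
    def test_boundary_value_passes(self, default_phantom):
        ss = default_phantom
        rx = pp.ladder_prescription(66.0)
        wl = pp.nsclc_wishlist()
        dose = np.where(ss["patient"].ravel(), 1.07 * 66.0, 0.0)
        # neutralize the mean constraint for the boundary check on max
        dose[ss.indices("lungs_minus_gtv")] = 0.0
        plan = Plan(np.zeros(1), dose, rx)
        checks = {c.volume: c for c in pp.check_hard_constraints(plan, wl, ss, rx)}
        assert checks["patient"].passed
        assert checks["patient"].margin == pytest.approx(0.0, abs=1e-9)

    def test_lung_mean_violation_detected(self, default_phantom):
        ss = default_phantom
        rx = pp.ladder_prescription(66.0)
        wl = pp.nsclc_wishlist()
        dose = np.zeros(ss.grid.n_voxels)
        dose[ss.indices("lungs_minus_gtv")] = 19.5
        plan = Plan(np.zeros(1), dose, rx)
        checks = {c.volume: c for c in pp.check_hard_constraints(plan, wl, ss, rx)}
        assert not checks["lungs_minus_gtv"].passed
        assert checks["lungs_minus_gtv"].value == pytest.approx(19.5)

    def test_zero_dose_satisfies_all_upper_bounds(self, default_phantom):
        ss = default_phantom
        rx = pp.ladder_prescription(66.0)
        plan = Plan(np.zeros(1), np.zeros(ss.grid.n_voxels), rx)
        assert all(c.passed for c in
                   pp.check_hard_constraints(plan, pp.nsclc_wishlist(), ss, rx))


class TestConditionalTargetVolume:
    def test_cord_far_from_target_uses_ptv(self, default_phantom):
        assert pp.select_target_volume_for_ptv_objective(default_phantom) == "ptv"

    def test_overlap_switches_to_cord_subtracted_target(self):
        ss = pp.build_phantom(pp.PhantomConfig(
            tumor_radius=14.0, tumor_center=(14.0, -44.0, 0.0)))
        assert pp.select_target_volume_for_ptv_objective(ss) == "ptv_minus_cord5"

    def test_single_shared_voxel_counts_as_close(self, default_phantom):
        ss = default_phantom
        cord5 = ss["cord_plus_5mm"].copy()
        ptv = ss["ptv"]
        try:
            # graft one PTV voxel into the cord expansion: tangency
            ss.masks["cord_plus_5mm"] = cord5.copy()
            ss.masks["cord_plus_5mm"][tuple(np.argwhere(ptv)[0])] = True
            assert pp.select_target_volume_for_ptv_objective(ss) == "ptv_minus_cord5"
        finally:
            ss.masks["cord_plus_5mm"] = cord5
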