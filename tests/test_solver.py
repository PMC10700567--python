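"""Direct-collocation redundancy solver: transcription structure, objective
arithmetic, analytic toy solutions, oracle equivalence, residual bounds."""

import numpy as np
import pytest
from scipy.optimize import minimize

from cyclesim.solver import (
    CollocationGrid,
    ObjectiveConfig,
    build_problem,
    objective_value,
    solve,
    static_optimization_oracle,
)
from tests.conftest import make_toy_problem


class TestGridAndCounts:
    def test_default_grid_structure(self):
        grid = CollocationGrid.from_cadence(85.0, n_per_rev=51)
        grid.validate()
        period = 60.0 / 85.0
        assert grid.n_nodes == 64  # 13 lead-in intervals + 51 revolution nodes
        assert grid.times[grid.tdc_index] == pytest.approx(0.0, abs=1e-12)
        assert grid.times[grid.end_index] == pytest.approx(period, abs=1e-9)
        assert grid.times[0] == pytest.approx(-0.26 * period, abs=1e-9)

    def test_tdc_not_a_node_rejected(self):
        grid = CollocationGrid.from_cadence(85.0, n_per_rev=21)
        grid.times = grid.times + 1e-3  # shift TDC off the grid
        with pytest.raises(ValueError, match="TDC"):
            grid.validate()

    def test_toy_variable_and_constraint_counts(self):
        # 1 DOF, 1 rigid muscle, 1 reserve: N*(e+a+u) variables;
        # N moment rows + (N-1) activation defects + 1 initial tie
        grid, prob, _ = make_toy_problem(n_per_rev=21)
        N = grid.n_nodes
        assert prob.n_var == 3 * N
        assert prob.n_con == N + (N - 1) + 1

    def test_dof_without_actuation_rejected(self):
        with pytest.raises(ValueError, match="neither a muscle nor an actuator"):
            grid, prob, _ = make_toy_problem(n_muscles=0, with_reserve=False)

    def test_j1_j2_share_constraints(self, mid_trial, mid_dynamics):
        meta, model, trial = mid_trial
        moments, inter = mid_dynamics
        grid = CollocationGrid.from_cadence(meta.cadence_rpm, n_per_rev=21)
        p1 = build_problem(model, trial, moments, ObjectiveConfig(mode="J1"), grid,
                           inter=inter)
        p2 = build_problem(model, trial, moments, ObjectiveConfig(mode="J2"), grid,
                           inter=inter)
        assert p1.n_con == p2.n_con and p1.n_var == p2.n_var
        x = np.clip(p1.initial_guess(), p1.lb, p1.ub)
        assert np.allclose(p1.constraints(x), p2.constraints(x))
        assert p2.objective(x) > p1.objective(x)  # penalty term only


class TestObjectiveArithmetic:
    def test_zero_everything(self):
        cfg = ObjectiveConfig(mode="J2")
        t = np.linspace(0, 1, 11)
        z = np.zeros((1, 11))
        assert objective_value(z, z, z, [np.zeros(11), np.zeros(11)], cfg, t) == 0.0

    def test_single_muscle_half_excitation(self):
        # w1=2, e=0.5 over 1 s, no actuators, rigid tendon: J1 = 2*0.25 = 0.5
        cfg = ObjectiveConfig(mode="J1", w1=2.0)
        t = np.linspace(0, 1, 101)
        e = np.full((1, 101), 0.5)
        val = objective_value(e, np.zeros((0, 101)), np.zeros((0, 101)), [], cfg, t)
        assert val == pytest.approx(0.5, abs=1e-12)

    def test_ftf_penalty_difference(self):
        # constant F_tf = 100 N on both legs for 1 s with w3 = 1e-3:
        # J2 - J1 = 1e-3 * 2 * 100^2 * 1 = 20
        t = np.linspace(0, 1, 101)
        e = np.full((1, 101), 0.5)
        legs = [np.full(101, 100.0), np.full(101, 100.0)]
        j1 = objective_value(e, None, None, [], ObjectiveConfig(mode="J1"), t)
        j2 = objective_value(e, None, None, legs, ObjectiveConfig(mode="J2"), t)
        assert j2 - j1 == pytest.approx(20.0, abs=1e-9)

    def test_j2_dominates_j1_for_any_trajectory(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 0.8, 37)
        for _ in range(20):
            e = rng.uniform(0, 1, (4, 37))
            u = rng.uniform(-1, 1, (2, 37))
            zd = rng.normal(0, 3, (3, 37))
            legs = [rng.normal(0, 800, 37), rng.normal(0, 800, 37)]
            j1 = objective_value(e, u, zd, [], ObjectiveConfig(mode="J1"), t)
            j2 = objective_value(e, u, zd, legs, ObjectiveConfig(mode="J2"), t)
            assert j2 >= j1

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveConfig(w1=-1.0).validate()


class TestToySolutions:
    def test_single_muscle_matches_analytic(self):
        grid, prob, cfg = make_toy_problem(n_per_rev=21, demand=20.0,
                                           with_reserve=False)
        sol = solve(prob, cfg)
        a_expected = (20.0 - 0.05 * 5.0) / (0.05 * 900.0)
        assert np.allclose(sol.activations[0], a_expected, atol=1e-3)
        assert np.abs(sol.moment_residuals).max() < 0.05  # N*m

    def test_two_identical_muscles_split_equally(self):
        grid, prob, cfg = make_toy_problem(n_per_rev=21, demand=30.0, n_muscles=2,
                                           with_reserve=False)
        sol = solve(prob, cfg)
        assert np.max(np.abs(sol.activations[0] - sol.activations[1])) < 1e-4

    def test_initial_excitation_activation_tie(self):
        grid, prob, cfg = make_toy_problem(n_per_rev=21, demand=20.0)
        sol = solve(prob, cfg)
        assert sol.excitations[0, 0] == pytest.approx(sol.activations[0, 0], abs=1e-3)

    def test_fast_dynamics_limit_matches_static_optimization(self):
        """With near-instant activation dynamics and rigid tendons, the
        collocation optimum collapses onto the per-node static optimum."""
        grid = CollocationGrid.from_cadence(80.0, n_per_rev=21)
        N = grid.n_nodes
        demand = 25.0 + 12.0 * np.sin(2 * np.pi * grid.times / (60.0 / 80.0))
        from cyclesim.model import HillCurves
        from cyclesim.solver import ActuatorChannel, CollocationProblem, MuscleChannel
        rng = np.random.default_rng(2)
        muscles = []
        for i, (fm, r) in enumerate([(900.0, 0.05), (1400.0, 0.04), (600.0, 0.06)]):
            ka = fm * (0.85 + 0.1 * np.sin(grid.times * 3.0 + i))
            muscles.append(MuscleChannel(
                name=f"m{i}", f_max=fm, tau_act=1e-4, tau_deact=1e-4, rigid=True,
                arms={"dof1": np.full(N, r)}, kappa_act=ka, kappa_pas=np.full(N, 2.0)))
        cfg = ObjectiveConfig(mode="J1", w2=0.0)
        prob = CollocationProblem(grid, muscles, {"dof1": demand},
                                  [ActuatorChannel("res", "dof1", 1.0)], cfg,
                                  HillCurves())
        sol = solve(prob, cfg)

        # independent per-node oracle: SLSQP on min sum(a^2) s.t. balance
        a_oracle = np.zeros((3, N))
        for k in range(N):
            A = np.array([[m.arms["dof1"][k] * m.kappa_act[k] for m in muscles]])
            b = demand[k] - sum(m.arms["dof1"][k] * m.kappa_pas[k] for m in muscles)
            res = minimize(lambda a: float(a @ a), np.full(3, 0.2), jac=lambda a: 2 * a,
                           method="SLSQP", bounds=[(0, 1)] * 3,
                           constraints=[{"type": "eq",
                                         "fun": lambda a, A=A, b=b: A @ a - b,
                                         "jac": lambda a, A=A: A}],
                           options={"ftol": 1e-12, "maxiter": 200})
            a_oracle[:, k] = res.x
        rms = np.sqrt(np.mean((sol.activations - a_oracle) ** 2))
        assert rms < 0.02


@pytest.fixture(scope="module")
def small_solves(mid_trial, mid_dynamics):
    meta, model, trial = mid_trial
    moments, inter = mid_dynamics
    grid = CollocationGrid.from_cadence(meta.cadence_rpm, n_per_rev=21)
    p1 = build_problem(model, trial, moments, ObjectiveConfig(mode="J1"), grid,
                       inter=inter)
    s1 = solve(p1)
    p2 = build_problem(model, trial, moments, ObjectiveConfig(mode="J2"), grid,
                       inter=inter)
    s2 = solve(p2, x0=s1.x_raw)
    return grid, p1, s1, p2, s2


class TestFullTrialSolve:

    def test_moment_residuals_within_tolerance(self, small_solves):
        grid, p1, s1, _, _ = small_solves
        # constraint tolerance 1e-3 on rows scaled by 50 N*m
        assert np.abs(s1.moment_residuals).max() <= 1e-3 * max(p1.row_scale)

    def test_bounds_respected(self, small_solves):
        _, _, s1, _, s2 = small_solves
        for s in (s1, s2):
            assert np.all(s.activations >= -1e-12) and np.all(s.activations <= 1 + 1e-12)
            assert np.all(s.excitations >= -1e-12) and np.all(s.excitations <= 1 + 1e-12)
            assert np.all(np.abs(s.controls) <= 1 + 1e-12)

    def test_total_equals_active_plus_passive(self, small_solves):
        _, _, s1, _, _ = small_solves
        assert np.allclose(s1.force_total, s1.force_active + s1.force_passive)

    def test_forces_nonnegative_active(self, small_solves):
        _, _, s1, _, s2 = small_solves
        assert np.all(s1.force_active >= -1e-9)
        assert np.all(s2.force_active >= -1e-9)

    def test_j2_objective_exceeds_j1_on_same_variables(self, small_solves):
        _, p1, s1, p2, _ = small_solves
        assert p2.objective(s1.x_raw) >= p1.objective(s1.x_raw)

    def test_deterministic_resolve(self, small_solves, mid_trial, mid_dynamics):
        grid, p1, s1, _, _ = small_solves
        meta, model, trial = mid_trial
        moments, inter = mid_dynamics
        p1b = build_problem(model, trial, moments, ObjectiveConfig(mode="J1"), grid,
                            inter=inter)
        s1b = solve(p1b)
        assert np.array_equal(s1.activations, s1b.activations)
        assert s1.objective == s1b.objective


class TestStaticOptimizationOracle:
    def test_zero_demand_zero_activations(self, mid_trial):
        # zero feasible only when no passive/damping torques need cancelling
        meta, _, trial = mid_trial
        from cyclesim.dynamics import NetMoments
        from cyclesim.model import HillCurves, generic_model, scale_model
        nopass = scale_model(
            generic_model(curves=HillCurves(fp_at_optimal=1e-12, fiber_damping=0.0)),
            meta.height_m, meta.mass_kg)
        t = trial.kin.time[::8]
        zero = NetMoments(time=trial.kin.time,
                          moments={d: np.zeros_like(trial.kin.time) for d in
                                   ("hip_flexion_r", "knee_flexion_r",
                                    "ankle_dorsiflexion_r")})
        A = static_optimization_oracle(nopass, trial, zero, times=t)
        assert np.max(A) < 1e-3

    def test_feasible_on_synthetic_trial(self, mid_trial, mid_dynamics):
        meta, model, trial = mid_trial
        moments, _ = mid_dynamics
        t = trial.kin.time[:: 16]
        A = static_optimization_oracle(model, trial, moments, times=t,
                                       include_reserves=True)
        assert A.shape == (16, len(t))
        assert np.all(A >= 0.0) and np.all(A <= 1.0)
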