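"""External loads, moment arms, static optimization, joint reactions."""

import numpy as np
import pytest
import sympy as sp
from scipy.optimize import LinearConstraint, minimize

from osteotraj import statics
from osteotraj.kinematics import Posture, pose_limb
from osteotraj.statics import (
    Actuator,
    DOFS,
    _box_least_norm,
    actuator_force_directions,
    actuator_point_forces,
    build_external_loads,
    moment_arm,
)


class TestExternalLoads:
    def test_grf_is_one_body_weight_vertical(self, model, external_loads):
        assert np.allclose(external_loads.grf[:2], 0.0)
        # 1.56 kg * 9.81 m/s^2
        assert external_loads.grf[2] == pytest.approx(15.304, abs=5e-4)

    def test_mediolateral_moment_formula(self, model, posed_start, external_loads):
        bw = model.body_weight
        expected = bw * (posed_start.cop[1] - posed_start.com[1])
        assert external_loads.m_x == pytest.approx(expected, rel=1e-12)
        # direct evaluation at the reference offsets
        assert 1.56 * 9.81 * 0.020 == pytest.approx(0.30607, abs=1e-4)

    def test_applied_moment_closes_global_equilibrium(self, model, posed_start, external_loads):
        # gravity at the COM + GRF at the COP + applied pes moment = null wrench
        g = model.gravity
        W = np.array([0.0, 0.0, -model.body_mass * g])
        F = external_loads.grf + W
        M = (
            np.cross(posed_start.com, W)
            + np.cross(posed_start.cop, external_loads.grf)
            + external_loads.applied_moment
        )
        assert np.allclose(F, 0.0, atol=1e-12)
        assert np.allclose(M, 0.0, atol=1e-12)

    def test_zero_offset_means_zero_moment(self, model, posed_start, external_loads):
        if abs(posed_start.cop[1] - posed_start.com[1]) < 1e-12:
            assert external_loads.m_x == pytest.approx(0.0, abs=1e-12)
        # the x-residual correction reflects the (repaired) COP-COM x offset
        assert abs(external_loads.m_y) <= model.body_weight * 2e-3


class TestMomentArm:
    def test_matches_symbolic_derivative_for_knee_crossing_path(self, model):
        # two-point path: femur-fixed P1, tibia-fixed P2; L(theta) has a
        # closed form under a pure knee hinge rotation
        p1 = np.array([0.012, -0.0045, -0.073])  # thigh frame
        p2 = np.array([0.014, 0.0, -0.011])  # shank frame
        act = Actuator("probe", "muscle", [("thigh", p1), ("shank", p2)], f_max=1.0)
        posture = Posture(-90.0, 0, 0, 60.0, 0.0, 0.0)

        th = sp.symbols("theta")
        c = sp.Matrix(model.joints["knee"].centre)
        R = sp.Matrix([[sp.cos(th), 0, sp.sin(th)], [0, 1, 0], [-sp.sin(th), 0, sp.cos(th)]])
        insertion = c + R * sp.Matrix(p2)
        L = sp.sqrt(sum((sp.Matrix(p1) - insertion)[i] ** 2 for i in range(3)))
        dL = sp.lambdify(th, sp.diff(L, th))(np.radians(60.0))

        r = moment_arm(act, model, posture, "knee_flexion")
        assert r == pytest.approx(-dL, rel=1e-6)

    def test_actuator_crossing_no_joint_has_zero_arms(self, model, start_posture):
        act = Actuator(
            "intra", "muscle",
            [("thigh", np.array([0.0, 0.0, -0.02])), ("thigh", np.array([0.0, 0.0, -0.05]))],
        )
        for dof in DOFS:
            assert moment_arm(act, model, start_posture, dof) == 0.0

    def test_extension_positive_convention_flips_flexion_coordinates(self, model, start_posture):
        act = next(a for a in model.actuators if a.name == "FMTM")
        r_coord = moment_arm(act, model, start_posture, "knee_flexion")
        r_ext = moment_arm(act, model, start_posture, "knee_flexion", "extension_positive")
        assert r_ext == -r_coord
        assert r_ext > 0  # a knee extensor


class TestStaticOptimizationSolver:
    def test_single_actuator_closed_form(self):
        # one hinge DOF: a * F_max * r = -M_ext
        A = np.array([[30.597 * 0.01]])
        b = np.array([0.15])
        x, _ = _box_least_norm(A, b, np.zeros(1), np.ones(1))
        assert x[0] == pytest.approx(0.15 / (30.597 * 0.01), abs=1e-9)
        assert x[0] == pytest.approx(0.49024, abs=1e-5)

    def test_two_identical_actuators_split_evenly(self):
        A = np.array([[0.30597, 0.30597]])
        b = np.array([0.15])
        x, _ = _box_least_norm(A, b, np.zeros(2), np.ones(2))
        assert x[0] == pytest.approx(x[1], abs=1e-12)
        assert x[0] == pytest.approx(0.49024 / 2, abs=1e-5)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_generic_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, n = 3, 8
        A = rng.normal(0, 1, (m, n))
        x_feas = rng.uniform(0.05, 0.95, n)
        b = A @ x_feas  # guaranteed feasible
        lb, ub = np.zeros(n), np.ones(n)
        x, g = _box_least_norm(A, b, lb, ub)
        assert np.abs(g).max() < 1e-8 * max(1.0, np.abs(b).max())

        res = minimize(
            lambda y: 0.5 * y @ y,
            np.clip(x_feas, 0.01, 0.99),
            jac=lambda y: y,
            bounds=[(0.0, 1.0)] * n,
            constraints=[LinearConstraint(A, b, b)],
            method="SLSQP",
            options=dict(maxiter=500, ftol=1e-16),
        )
        # SLSQP's success flag is occasionally pessimistic at tight ftol;
        # the oracle comparison is the objective/solution agreement itself
        assert np.abs(A @ res.x - b).max() < 1e-8
        assert 0.5 * x @ x == pytest.approx(0.5 * res.x @ res.x, abs=1e-8)
        assert np.abs(x - res.x).max() < 1e-6

    def test_activation_bounds_and_balance(self, activation_solution):
        a = np.array(list(activation_solution.activations.values()))
        assert (a >= -1e-12).all() and (a <= 1 + 1e-12).all()
        assert np.abs(activation_solution.residuals).max() < 1e-8
        assert abs(activation_solution.mtp_reserve_moment) <= 1000.0

    def test_activations_invariant_to_actuator_ordering(self, model, posed_start, external_loads):
        sol1 = statics.solve_static_optimization(model, posed_start, external_loads)
        reordered = list(reversed(model.actuators))
        sol2 = statics.solve_static_optimization(
            model, posed_start, external_loads, actuators=reordered
        )
        for name in sol1.activations:
            assert sol1.activations[name] == pytest.approx(sol2.activations[name], abs=1e-9)

    def test_doubling_fmax_halves_activations(self, model, posed_start, external_loads):
        import copy

        sol1 = statics.solve_static_optimization(model, posed_start, external_loads)
        # the exact-scaling argument needs the upper bounds inactive
        assert max(sol1.activations.values()) < 1.0
        doubled = copy.deepcopy(model.actuators)
        for a in doubled:
            a.f_max *= 2.0
        sol2 = statics.solve_static_optimization(
            model, posed_start, external_loads, actuators=doubled, reserve_capacity=2000.0
        )
        for name, a1 in sol1.activations.items():
            assert sol2.activations[name] == pytest.approx(a1 / 2.0, abs=1e-8)
            assert sol2.forces[name] == pytest.approx(sol1.forces[name], abs=1e-6)

    def test_per_muscle_sensitivity_mode_same_solver_path(self, model, posed_start,
                                                          external_loads):
        """Muscle-specific maximum forces run through the identical
        solver with only f_max changed; ligaments keep 2 BW."""
        from osteotraj._actuators import TABLE_FMAX, build_actuators

        acts = build_actuators(model, f_max_mode="per_muscle")
        by_name = {a.name: a for a in acts}
        assert by_name["FMTI"].f_max == pytest.approx(92.110)
        assert by_name["AMB"].f_max == pytest.approx(1.112)
        assert by_name["KMCL"].f_max == pytest.approx(2.0 * model.body_weight)
        sol = statics.solve_static_optimization(
            model, posed_start, external_loads, actuators=acts
        )
        assert np.abs(sol.residuals).max() < 1e-8
        for name, a in sol.activations.items():
            assert -1e-12 <= a <= 1 + 1e-12
        # stronger muscles need lower activations for the same moments
        total_force = sum(sol.forces.values())
        assert total_force > 0

    def test_infeasible_posture_reports_violated_dofs(self, model):
        # deep crouch beyond plantarflexor capacity
        p = Posture(-40.0, 5.0, 20.0, 103.0, 124.0, 70.0)
        posed = pose_limb(model, p, validate=False)
        loads = build_external_loads(posed, model)
        with pytest.raises(statics.InfeasibleError) as exc:
            statics.solve_static_optimization(model, posed, loads)
        assert len(exc.value.dofs) >= 1


class TestForceDirections:
    def test_straight_vertical_path(self, model, posed_start):
        act = Actuator(
            "v", "muscle",
            [("pelvis", np.array([0.0, 0.0, 0.1])), ("pelvis", np.array([0.0, 0.0, 0.0]))],
        )
        d_o, d_i = actuator_force_directions(act, posed_start)
        assert np.allclose(d_o, [0, 0, -1])
        assert np.allclose(d_i, [0, 0, 1])

    def test_right_angle_via_point(self, model, posed_start):
        act = Actuator(
            "L", "muscle",
            [
                ("pelvis", np.array([0.0, 0.0, 0.1])),
                ("pelvis", np.array([0.0, 0.0, 0.0])),
                ("pelvis", np.array([0.1, 0.0, 0.0])),
            ],
        )
        d_o, d_i = actuator_force_directions(act, posed_start)
        assert abs(d_o @ d_i) < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_polyline_tangency(self, model, posed_start, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 0.05, (5, 3))
        act = Actuator("r", "muscle", [("pelvis", p) for p in pts])
        d_o, d_i = actuator_force_directions(act, posed_start)
        assert np.linalg.norm(d_o) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(d_i) == pytest.approx(1.0, abs=1e-12)
        # tangency: finite difference of arc position along the first leg
        t = (pts[1] - pts[0]) / np.linalg.norm(pts[1] - pts[0])
        assert np.allclose(d_o, t, atol=1e-12)

    def test_path_force_set_is_self_equilibrated(self, model, posed_start):
        act = next(a for a in model.actuators if a.name == "FDL")
        entries = actuator_point_forces(act, 10.0, posed_start)
        total = sum(f for _, _, f in entries)
        assert np.allclose(total, 0.0, atol=1e-12)


class TestJointReactions:
    def test_segment_equilibrium(self, joint_loads):
        assert max(joint_loads.segment_residuals.values()) < 1e-9

    def test_hip_reaction_moment_vanishes(self, joint_loads):
        # ball-and-socket: the solved muscle set leaves no moment for
        # the joint structure to carry
        assert np.abs(joint_loads.moments["hip"]).max() < 1e-3

    def test_matches_hand_newton_euler_for_pes(self, model, posed_start, activation_solution,
                                               external_loads, joint_loads):
        # independent distal-segment balance: reaction at the MTP equals
        # minus everything applied to the pes
        g = model.gravity
        seg = model.segments["pes"]
        acc_f = external_loads.grf + np.array([0, 0, -seg.mass * g])
        act_lookup = {a.name: a for a in model.actuators}
        for name, tension in activation_solution.forces.items():
            if tension == 0.0:
                continue
            for seg_name, pt, f in actuator_point_forces(act_lookup[name], tension, posed_start):
                if seg_name == "pes":
                    acc_f = acc_f + f
        assert np.allclose(joint_loads.forces["mtp"], -acc_f, atol=1e-9)

    def test_whole_model_force_closure(self, model, posed_start, activation_solution,
                                       external_loads, joint_loads):
        # hip reaction + pelvis-side loads (gravity on pelvis + muscle
        # forces on the pelvis) must close the global balance
        g = model.gravity
        act_lookup = {a.name: a for a in model.actuators}
        pelvis_f = np.array([0.0, 0.0, -model.segments["pelvis"].mass * g])
        for name, tension in activation_solution.forces.items():
            if tension == 0.0:
                continue
            for seg_name, pt, f in actuator_point_forces(act_lookup[name], tension, posed_start):
                if seg_name == "pelvis":
                    pelvis_f = pelvis_f + f
        assert np.allclose(pelvis_f - joint_loads.forces["hip"], 0.0, atol=1e-9)
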