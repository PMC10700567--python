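"""Newton-Euler inverse dynamics: closed-form statics, consistency, power."""

import math

import numpy as np
import pytest

from cyclesim.dynamics import (
    PedalLoad,
    crank_power,
    joint_power_work,
    net_joint_moments,
    pedal_force_check,
    saddle_closure,
)
from cyclesim.kinematics import CrankGeometry, TrialKinematics, segment_revolutions
from cyclesim.model import default_model


def _static_kinematics(model, geom, hip=0.9, knee=1.3, ankle=0.0, n=25):
    t = np.linspace(0.0, 1.0, n)
    crank = np.linspace(0.0, 0.1, n)  # placeholder, strictly increasing
    angles = {}
    for side in ("r", "l"):
        angles[f"hip_flexion_{side}"] = np.full(n, hip)
        angles[f"knee_flexion_{side}"] = np.full(n, knee)
        angles[f"ankle_dorsiflexion_{side}"] = np.full(n, ankle)
    for dof in ("pelvis_x", "pelvis_y", "pelvis_tilt"):
        angles[dof] = np.zeros(n)
    return TrialKinematics(t, crank, angles)


def _zero_load(n=25):
    z = np.zeros(n)
    return PedalLoad(time=np.linspace(0, 1, n), fx=z, fy=z.copy(),
                     px=z.copy(), py=z.copy())


class TestStatics:
    def test_zero_gravity_zero_load_equilibrium(self):
        model = default_model()
        model.gravity = 0.0
        geom = CrankGeometry()
        kin = _static_kinematics(model, geom)
        mom, _ = net_joint_moments(kin, _zero_load(), model, geom)
        for d, series in mom.moments.items():
            assert np.allclose(series, 0.0, atol=1e-9), d

    def test_gravity_statics_matches_hand_formula(self):
        """Static posture, gravity only: each joint moment equals the summed
        m*g*(horizontal COM lever) of the segments distal to it."""
        model = default_model()
        geom = CrankGeometry()
        hip, knee, ankle = 0.9, 1.3, 0.0
        kin = _static_kinematics(model, geom, hip, knee, ankle)
        mom, _ = net_joint_moments(kin, _zero_load(), model, geom)

        g = model.gravity
        hx, hy = geom.saddle_position
        thigh, shank, foot = (model.segments[f"{s}_r"] for s in ("thigh", "shank", "foot"))
        alpha, beta = hip, hip - knee
        psi = beta + ankle
        knee_pt = np.array([hx + thigh.length * math.sin(alpha),
                            hy - thigh.length * math.cos(alpha)])
        ankle_pt = knee_pt + shank.length * np.array([math.sin(beta), -math.cos(beta)])
        com_t = np.array([hx + thigh.com_offset * math.sin(alpha),
                          hy - thigh.com_offset * math.cos(alpha)])
        com_s = knee_pt + shank.com_offset * np.array([math.sin(beta), -math.cos(beta)])
        com_f = ankle_pt + foot.com_offset * np.array([math.cos(psi), math.sin(psi)])

        # CCW joint torques; flexion-positive mapping: hip +, knee -, ankle +
        m_ankle = -foot.mass * g * (com_f[0] - ankle_pt[0]) * -1.0
        # torque on foot about ankle from gravity must be balanced: tau =
        # +m g * (x_com - x_joint) about z for force (0, -mg): cross(r, F) =
        # rx*(-mg) -> tau_muscle = +m g rx
        m_ankle = foot.mass * g * (com_f[0] - ankle_pt[0])
        tau_knee_ccw = (shank.mass * g * (com_s[0] - knee_pt[0])
                        + foot.mass * g * (com_f[0] - knee_pt[0]))
        m_hip = (thigh.mass * g * (com_t[0] - hx)
                 + shank.mass * g * (com_s[0] - hx)
                 + foot.mass * g * (com_f[0] - hx))
        assert mom["ankle_dorsiflexion_r"][5] == pytest.approx(m_ankle, abs=1e-9)
        assert mom["knee_flexion_r"][5] == pytest.approx(-tau_knee_ccw, abs=1e-9)
        assert mom["hip_flexion_r"][5] == pytest.approx(m_hip, abs=1e-9)

    def test_straight_leg_vertical_force_lever(self):
        """Straight vertical leg, weightless, vertical pedal push: the ankle
        moment equals force x horizontal lever from ankle to the application
        point (single free-body closed form)."""
        model = default_model()
        model.gravity = 0.0
        geom = CrankGeometry()
        kin = _static_kinematics(model, geom, hip=0.0, knee=0.0, ankle=0.0)
        n = len(kin.time)
        # drive convention: foot pushes down with F at the pedal point
        F = 100.0
        hx, hy = geom.saddle_position
        L = model.segments["thigh_r"].length + model.segments["shank_r"].length
        lever = model.segments["foot_r"].length  # foot horizontal at psi=0
        load = PedalLoad(time=kin.time, fx=np.zeros(n), fy=np.full(n, -F),
                         px=np.full(n, hx + lever), py=np.full(n, hy - L))
        mom, inter = net_joint_moments(kin, load, model, geom)
        # reaction +F up at horizontal lever ahead of the ankle -> the
        # muscles must supply a plantarflexion (negative) moment F * lever
        assert mom["ankle_dorsiflexion_r"][5] == pytest.approx(-F * lever, abs=1e-9)
        fx, fy = pedal_force_check(kin, model, geom, inter)
        assert np.allclose(fx, load.fx, atol=1e-6)
        assert np.allclose(fy, load.fy, atol=1e-6)

    def test_grid_mismatch_error(self):
        model = default_model()
        geom = CrankGeometry()
        kin = _static_kinematics(model, geom)
        load = _zero_load()
        load.time = load.time + 0.5
        with pytest.raises(ValueError, match="grid"):
            net_joint_moments(kin, load, model, geom)


class TestCrankPower:
    def test_constant_tangential_closed_form(self):
        # F * r * omega = 100 N * 0.1725 m * 8.3776 rad/s = 144.51 W
        geom = CrankGeometry(crank_length=0.1725)
        omega = 80.0 / 60.0 * 2 * math.pi
        t = np.linspace(0, 3 * 60 / 80.0, 1000)
        th = omega * t
        tx, ty = np.cos(th), -np.sin(th)
        load = PedalLoad(time=t, fx=100.0 * tx, fy=100.0 * ty,
                         px=np.zeros_like(t), py=np.zeros_like(t))
        p = crank_power(load, th, geom, time=t)
        assert p == pytest.approx(144.51, abs=0.05)

    def test_pure_radial_force_zero_power(self):
        geom = CrankGeometry()
        omega = 8.0
        t = np.linspace(0, 2.0, 2000)
        th = omega * t
        rx, ry = np.sin(th), np.cos(th)
        load = PedalLoad(time=t, fx=523.0 * rx, fy=523.0 * ry,
                         px=np.zeros_like(t), py=np.zeros_like(t))
        assert crank_power(load, th, geom, time=t) == pytest.approx(0.0, abs=1e-6)

    def test_less_than_one_revolution_errors(self):
        geom = CrankGeometry()
        t = np.linspace(0, 0.3, 100)
        th = 8.0 * t
        load = PedalLoad(time=t, fx=np.ones(100), fy=np.ones(100),
                         px=np.zeros(100), py=np.zeros(100))
        with pytest.raises(ValueError):
            crank_power(load, th, geom, time=t)


class TestTrialConsistency:
    def test_energy_balance_within_one_percent(self, mid_trial, mid_dynamics):
        """Over a complete revolution of a dynamically consistent trial the
        joint work equals the crank work done on the pedal, within 1%."""
        meta, model, trial = mid_trial
        moments, _ = mid_dynamics
        wins = segment_revolutions(trial.kin.crank_angle)
        i0, i1 = wins[0]
        w_joints = joint_power_work(trial.kin, moments, (i0, i1), side="r")
        # crank work by the right leg = integral of drive force . pedal velocity
        load = trial.loads["r"]
        t = trial.kin.time[i0:i1 + 1]
        vx = np.gradient(load.px, trial.kin.time)[i0:i1 + 1]
        vy = np.gradient(load.py, trial.kin.time)[i0:i1 + 1]
        w_crank = np.trapezoid(load.fx[i0:i1 + 1] * vx + load.fy[i0:i1 + 1] * vy, t)
        assert w_joints == pytest.approx(w_crank, rel=0.01)

    def test_action_reaction(self, mid_trial, mid_dynamics):
        meta, model, trial = mid_trial
        _, inter = mid_dynamics
        # force by thigh on shank at the knee is minus force by shank on
        # thigh; the recursion propagates F_knee into the thigh balance, so
        # re-deriving the hip force from the thigh free body must agree
        from cyclesim.dynamics import _chain_points
        pts = _chain_points(trial.kin, trial.geom, model, "r")
        thigh = model.segments["thigh_r"]
        atx, aty = pts["com_thigh"][2]
        F_kne = inter.on_distal["knee"]
        F_hip = inter.on_distal["hip"]
        assert np.allclose(F_hip[:, 0], thigh.mass * atx + F_kne[:, 0], atol=1e-9)
        assert np.allclose(
            F_hip[:, 1], thigh.mass * aty + thigh.mass * model.gravity + F_kne[:, 1],
            atol=1e-9)

    def test_forward_free_body_check(self, mid_trial, mid_dynamics):
        meta, model, trial = mid_trial
        _, inter = mid_dynamics
        fx, fy = pedal_force_check(trial.kin, model, trial.geom, inter, side="r")
        assert np.max(np.abs(fx - trial.loads["r"].fx)) < 1e-6
        assert np.max(np.abs(fy - trial.loads["r"].fy)) < 1e-6

    def test_saddle_closure_balances_pelvis(self, mid_trial):
        meta, model, trial = mid_trial
        sfx, sfy, _ = saddle_closure(trial.kin, trial.loads, model, trial.geom)
        # the stored trial saddle series is exactly this closure
        assert np.allclose(sfx, trial.saddle["fx"], atol=1e-9)
        assert np.allclose(sfy, trial.saddle["fy"], atol=1e-9)
        # and it carries most of body weight on average (seated cycling)
        bw = model.body_mass * model.gravity
        assert 0.4 * bw < np.mean(sfy) < 1.1 * bw
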