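"""Musculoskeletal model: rigidity rule, scaling, moment arms, Hill curves."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from cyclesim.model import (
    HillCurves,
    MTUParams,
    activation_rate,
    assign_tendon_rigidity,
    fiber_force,
    generic_model,
    moment_arm,
    mtu_length,
    scale_model,
    tendon_equilibrium_residual,
)


def _mtu(**kw):
    base = dict(name="test", f_max=1000.0, l_opt=0.1, l_slack=0.2,
                moment_arm_coeffs={"dof": [0.04]})
    base.update(kw)
    return MTUParams(**base)


class TestTendonRigidity:
    @pytest.mark.parametrize("l_slack,l_opt,expected", [
        (0.05, 0.10, True),   # slack shorter than optimal -> rigid
        (0.40, 0.05, False),  # long tendon -> compliant
        (0.10, 0.10, False),  # tie resolved as compliant ("shorter" is strict)
    ])
    def test_rule(self, l_slack, l_opt, expected):
        out = assign_tendon_rigidity(_mtu(l_slack=l_slack, l_opt=l_opt))
        assert out.rigid_tendon is expected
        assert out.l_slack == l_slack and out.l_opt == l_opt

    def test_invalid_l_opt(self):
        with pytest.raises(ValueError):
            assign_tendon_rigidity(_mtu(l_opt=-1.0))

    def test_every_model_mtu_obeys_rule(self, model75):
        for mtu in model75.mtus:
            assert mtu.rigid_tendon == (mtu.l_slack < mtu.l_opt)


class TestScaling:
    def test_identity(self, model75):
        scaled = scale_model(model75, model75.ref_height, model75.ref_mass)
        for name, seg in model75.segments.items():
            s = scaled.segments[name]
            assert s.mass == pytest.approx(seg.mass)
            assert s.length == pytest.approx(seg.length)
            assert s.inertia_z == pytest.approx(seg.inertia_z)
        for m0, m1 in zip(model75.mtus, scaled.mtus):
            assert m1.l_opt == pytest.approx(m0.l_opt)
            assert m1.f_max == m0.f_max

    def test_mass_doubling_conserves_total(self, model75):
        scaled = scale_model(model75, model75.ref_height, 2 * model75.ref_mass)
        tot0 = sum(s.mass for s in model75.segments.values())
        tot1 = sum(s.mass for s in scaled.segments.values())
        assert tot1 == pytest.approx(2 * tot0)
        for name, seg in model75.segments.items():
            assert scaled.segments[name].mass == pytest.approx(2 * seg.mass)

    def test_p01_ratios(self, model75):
        # P01: 169.0 cm, 60.4 kg against the 1.75 m / 75 kg generic model
        scaled = scale_model(model75, 1.690, 60.4)
        hr, mr = 1.690 / 1.75, 60.4 / 75.0
        assert scaled.segments["thigh_r"].length == pytest.approx(
            model75.segments["thigh_r"].length * hr)
        assert hr == pytest.approx(0.96571, abs=1e-4)
        assert mr == pytest.approx(0.80533, abs=1e-4)
        assert scaled.segments["shank_l"].mass == pytest.approx(
            model75.segments["shank_l"].mass * mr)
        assert scaled.mtus[0].l_opt == pytest.approx(model75.mtus[0].l_opt * hr)
        assert scaled.mtus[0].f_max == model75.mtus[0].f_max

    def test_residuals_track_body_weight(self, model75):
        scaled = scale_model(model75, 1.690, 60.4)
        res = [a for a in scaled.actuators if a.kind == "residual_force"
               and a.dof == "pelvis_y"][0]
        assert res.capacity == pytest.approx(60.4 * scaled.gravity)

    def test_invalid_inputs(self, model75):
        with pytest.raises(ValueError):
            scale_model(model75, -1.7, 75.0)


class TestMomentArmLengthConsistency:
    def test_reference_posture_length(self, model75):
        mtu = model75.mtu("soleus_r")
        L = mtu_length(mtu, model75.reference_posture, model75.reference_posture)
        assert L == pytest.approx(mtu.l_slack + mtu.l_opt * math.cos(mtu.pennation_opt))

    def test_constant_arm_linear_excursion(self):
        mtu = _mtu(moment_arm_coeffs={"dof": [0.04]})
        ref = {"dof": 0.0}
        L0 = mtu_length(mtu, {"dof": 0.0}, ref)
        L1 = mtu_length(mtu, {"dof": 0.5}, ref)
        assert L1 - L0 == pytest.approx(-0.04 * 0.5)

    def test_cubic_arm_matches_quadrature(self):
        coeffs = [0.03, -0.01, 0.005, -0.002]
        mtu = _mtu(moment_arm_coeffs={"dof": coeffs})
        ref = {"dof": 0.0}
        dL = mtu_length(mtu, {"dof": 1.0}, ref) - mtu_length(mtu, {"dof": 0.0}, ref)
        oracle, _ = quad(lambda q: -np.polynomial.polynomial.polyval(q, coeffs), 0.0, 1.0)
        assert dL == pytest.approx(oracle, abs=1e-9)

    def test_arm_is_minus_length_derivative(self, model75):
        # central finite difference over 100 random postures, all MTUs
        rng = np.random.default_rng(7)
        eps = 1e-6
        for mtu in model75.mtus_for_leg("r"):
            for dof in mtu.moment_arm_coeffs:
                for q0 in rng.uniform(0.0, 1.8, 8):
                    q = dict(model75.reference_posture)
                    qp = dict(q)
                    qm = dict(q)
                    qp[dof] = q0 + eps
                    qm[dof] = q0 - eps
                    fd = -(mtu_length(mtu, qp, model75.reference_posture)
                           - mtu_length(mtu, qm, model75.reference_posture)) / (2 * eps)
                    q[dof] = q0
                    assert fd == pytest.approx(moment_arm(mtu, dof, q0), abs=1e-6)

    def test_unknown_dof_raises(self, model75):
        with pytest.raises(KeyError):
            moment_arm(model75.mtu("soleus_r"), "hip_flexion_r", 0.5)

    def test_biceps_femoris_stays_knee_flexor(self, model75):
        # no spurious knee extension moments anywhere in 0..150 deg flexion
        q = np.linspace(0.0, math.radians(150.0), 301)
        for name in ("bifemlh_r", "bifemsh_r"):
            r = moment_arm(model75.mtu(name), "knee_flexion_r", q)
            assert np.all(r > 0.0)


class TestHillCurves:
    def test_normalization(self, curves):
        assert curves.fl(1.0) == pytest.approx(1.0, abs=1e-9)
        assert curves.fv(0.0) == pytest.approx(1.0, abs=1e-9)
        assert curves.fp(1.0) <= 0.02

    def test_passive_positive_and_increasing(self, curves):
        ln = np.linspace(0.4, 1.8, 100)
        fp = curves.fp(ln)
        assert np.all(fp >= 0.0)
        assert np.all(np.diff(fp) > 0.0)
        assert curves.fp(1.5) > curves.fp(1.2)

    def test_curve_derivatives_match_finite_differences(self, curves):
        eps = 1e-7
        for x in (0.7, 0.95, 1.2, 1.5):
            fd = (curves.fl(x + eps) - curves.fl(x - eps)) / (2 * eps)
            assert fd == pytest.approx(float(curves.dfl(x)), rel=1e-5, abs=1e-6)
        for v in (-0.6, -0.1, 0.3):
            fd = (curves.fv(v + eps) - curves.fv(v - eps)) / (2 * eps)
            assert fd == pytest.approx(float(curves.dfv(v)), rel=1e-5, abs=1e-6)
        for s in (0.0, 0.02, 0.05):
            fd = (curves.ft(s + eps) - curves.ft(s - eps)) / (2 * eps)
            assert fd == pytest.approx(float(curves.dft(s)), rel=1e-5)


class TestFiberForce:
    def test_zero_activation(self, curves):
        active, passive = fiber_force(0.0, 1.0, 0.0, _mtu(), curves)
        assert active == 0.0
        assert passive >= 0.0

    def test_isometric_max(self, curves):
        mtu = _mtu(pennation_opt=0.0)
        active, _ = fiber_force(1.0, 1.0, 0.0, mtu, curves)
        assert active == pytest.approx(mtu.f_max)

    def test_passive_bounds_and_monotonicity(self, curves):
        mtu = _mtu(pennation_opt=0.0)
        _, p10 = fiber_force(0.0, 1.0, 0.0, mtu, curves)
        _, p12 = fiber_force(0.0, 1.2, 0.0, mtu, curves)
        _, p15 = fiber_force(0.0, 1.5, 0.0, mtu, curves)
        assert p10 <= 0.02 * mtu.f_max
        assert p15 > p12

    def test_nonnegative_over_admissible_states(self, curves):
        rng = np.random.default_rng(0)
        mtu = _mtu(pennation_opt=0.2)
        a = rng.uniform(0, 1, 50)
        ln = rng.uniform(0.4, 1.8, 50)
        vn = rng.uniform(-0.95, 0.95, 50)
        active, passive = fiber_force(a, ln, vn, mtu, curves)
        assert np.all(active >= 0.0) and np.all(passive >= 0.0)

    def test_domain_error(self, curves):
        with pytest.raises(ValueError):
            fiber_force(1.5, 1.0, 0.0, _mtu(), curves)


class TestActivationRate:
    def test_equilibrium(self):
        assert activation_rate(0.5, 0.5, _mtu()) == 0.0

    def test_activation_bound(self):
        rate = float(activation_rate(1.0, 0.0, _mtu(tau_act=0.01)))
        assert 0.0 < rate <= 100.0 + 1e-6

    def test_deactivation_bound(self):
        rate = float(activation_rate(0.0, 1.0, _mtu(tau_deact=0.04)))
        assert -25.0 - 1e-6 <= rate < 0.0

    def test_smooth_at_crossing(self):
        mtu = _mtu()
        eps = 1e-9
        up = float(activation_rate(0.5 + eps, 0.5, mtu))
        dn = float(activation_rate(0.5 - eps, 0.5, mtu))
        assert abs(up + dn) < 1e-6  # odd and continuous through e == a


class TestTendonEquilibrium:
    def _compliant(self):
        return assign_tendon_rigidity(
            _mtu(l_opt=0.05, l_slack=0.25, pennation_opt=0.0))

    def test_unloaded_slack_equilibrium(self, curves):
        mtu = self._compliant()
        # fiber short enough that passive ~ 0; tendon exactly at slack length
        ln = 0.6
        l_mtu = mtu.l_slack + ln * mtu.l_opt
        r = tendon_equilibrium_residual(0.0, ln, 0.0, l_mtu, mtu, curves)
        # both sides are small (ft(0)=0, fp(0.6) ~ 5e-4): near-zero residual
        assert abs(r) < 1e-2 * mtu.f_max

    def test_bisection_oracle(self, curves):
        mtu = self._compliant()
        l_mtu = mtu.l_slack * 1.02 + mtu.l_opt  # stretched: tendon bears load
        root = brentq(
            lambda ln: float(tendon_equilibrium_residual(1.0, ln, 0.0, l_mtu, mtu, curves)),
            0.3, 1.9, xtol=1e-12)
        res = tendon_equilibrium_residual(1.0, root, 0.0, l_mtu, mtu, curves)
        assert abs(res) < 1e-6 * mtu.f_max

    def test_perturbation_sign_deterministic(self, curves):
        mtu = self._compliant()
        l_mtu = mtu.l_slack * 1.02 + mtu.l_opt
        root = brentq(
            lambda ln: float(tendon_equilibrium_residual(1.0, ln, 0.0, l_mtu, mtu, curves)),
            0.3, 1.9, xtol=1e-12)
        r1 = tendon_equilibrium_residual(1.0, root * 1.01, 0.0, l_mtu, mtu, curves)
        r2 = tendon_equilibrium_residual(1.0, root * 1.01, 0.0, l_mtu, mtu, curves)
        assert r1 == r2
        # longer fiber -> shorter tendon (less force) and more fiber force
        assert r1 < 0.0

    def test_rigid_tendon_rejected(self, curves):
        mtu = assign_tendon_rigidity(_mtu(l_opt=0.2, l_slack=0.1))
        with pytest.raises(ValueError):
            tendon_equilibrium_residual(0.5, 1.0, 0.0, 0.3, mtu, curves)


def test_model_validation_counts(model75):
    model75.validate()
    assert len(model75.mtus_for_leg("r")) == 16
    assert len(model75.mtus_for_leg("l")) == 16
    residuals = [a for a in model75.actuators if a.kind == "residual_force"]
    assert {a.dof for a in residuals} == {"pelvis_x", "pelvis_y", "pelvis_tilt"}
    # vertical residual alone supports one body weight
    ry = [a for a in residuals if a.dof == "pelvis_y"][0]
    assert ry.capacity == pytest.approx(model75.body_mass * model75.gravity)


def test_rigidity_mismatch_rejected(model75):
    import copy
    bad = copy.deepcopy(model75)
    bad.mtus[0].rigid_tendon = not bad.mtus[0].rigid_tendon
    with pytest.raises(ValueError, match="rigid-tendon rule"):
        bad.validate()
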