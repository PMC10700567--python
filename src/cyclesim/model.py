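"""Planar musculoskeletal model for seated-cycling simulation.

The model is a sagittal-plane lower-limb linkage (pelvis + thigh/shank/foot
per leg) actuated by 16 Hill-type muscle-tendon units (MTUs) per leg, plus
idealized reserve (joint torque) and residual (pelvis/saddle force)
actuators.  Muscle paths are represented by per-DOF moment-arm polynomials;
MTU length is defined by tendon excursion, which makes moment arms and
lengths consistent by construction.

Sign conventions: positive joint angles and moments are hip flexion, knee
flexion, and ankle dorsiflexion.  A muscle's moment arm is positive when its
force produces a positive moment about that DOF.

All Hill curves are continuous and differentiable everywhere, as required by
gradient-based direct collocation.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

GRAVITY = 9.80665

#: DOF names of the planar model, in canonical order.
PELVIS_DOFS = ("pelvis_x", "pelvis_y", "pelvis_tilt")
LEG_DOFS = ("hip_flexion", "knee_flexion", "ankle_dorsiflexion")


def leg_dof_names(side: str) -> tuple[str, ...]:
    """DOF names for one leg, ``side`` in {"r", "l"}."""
    return tuple(f"{d}_{side}" for d in LEG_DOFS)


# ---------------------------------------------------------------------------
# Hill curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillCurves:
    """Dimensionless Hill-type muscle and tendon characteristic curves.

    Active force-length: sum of three Gaussians, rescaled so fl(1) = 1
    exactly.  Force-velocity: smooth log-arcsinh form, rescaled so
    fv(0) = 1 exactly; the argument is fiber velocity normalized by the
    maximum shortening velocity (lengthening positive).  Passive
    force-length: a single exponential, strictly increasing and positive
    everywhere, with fp at optimal fiber length equal to ``fp_at_optimal``
    and fp(1 + ``passive_strain_iso``) = 1.  Tendon force-strain: an
    exponential reaching 1 at ``tendon_strain_iso``.
    """

    # active fl Gaussians: amplitude, center, width, width-slope
    fl_b1: tuple[float, ...] = (0.815, 0.433, 0.100)
    fl_b2: tuple[float, ...] = (1.055, 0.717, 1.000)
    fl_b3: tuple[float, ...] = (0.162, -0.030, 0.354)
    fl_b4: tuple[float, ...] = (0.0633, 0.200, 0.000)
    # force-velocity coefficients
    fv_d: tuple[float, float, float, float] = (-0.318, -8.149, -0.374, 0.886)
    # passive exponential
    fp_at_optimal: float = 0.010
    passive_strain_iso: float = 0.6
    # tendon exponential
    tendon_k: float = 35.0
    tendon_strain_iso: float = 0.049
    # maximum shortening velocity in optimal fiber lengths / s
    v_max: float = 10.0
    # parallel fiber damping (dimensionless force per normalized velocity);
    # regularizes the tendon equilibrium when activation vanishes
    fiber_damping: float = 0.1

    # -- active force-length ------------------------------------------------
    def _fl_raw(self, l):
        l = np.asarray(l, dtype=float)
        out = np.zeros_like(l)
        for b1, b2, b3, b4 in zip(self.fl_b1, self.fl_b2, self.fl_b3, self.fl_b4):
            w = b3 + b4 * l
            out = out + b1 * np.exp(-0.5 * (l - b2) ** 2 / w**2)
        return out

    def fl(self, l_norm):
        """Active force-length multiplier; fl(1) == 1 exactly."""
        return self._fl_raw(l_norm) / self._fl_raw(1.0)

    def dfl(self, l_norm):
        """d fl / d l_norm (analytic)."""
        l = np.asarray(l_norm, dtype=float)
        out = np.zeros_like(l)
        for b1, b2, b3, b4 in zip(self.fl_b1, self.fl_b2, self.fl_b3, self.fl_b4):
            w = b3 + b4 * l
            g = b1 * np.exp(-0.5 * (l - b2) ** 2 / w**2)
            # d/dl [-(l-b2)^2 / (2 w^2)] with w = b3 + b4 l
            darg = -(l - b2) / w**2 + (l - b2) ** 2 * b4 / w**3
            out = out + g * darg
        return out / self._fl_raw(1.0)

    def d2fl(self, l_norm):
        """Second derivative of the active force-length curve."""
        l = np.asarray(l_norm, dtype=float)
        out = np.zeros_like(l)
        for b1, b2, b3, b4 in zip(self.fl_b1, self.fl_b2, self.fl_b3, self.fl_b4):
            w = b3 + b4 * l
            g = b1 * np.exp(-0.5 * (l - b2) ** 2 / w**2)
            darg = -(l - b2) / w**2 + (l - b2) ** 2 * b4 / w**3
            d2arg = (-1.0 / w**2 + 4.0 * (l - b2) * b4 / w**3
                     - 3.0 * (l - b2) ** 2 * b4**2 / w**4)
            out = out + g * (darg**2 + d2arg)
        return out / self._fl_raw(1.0)

    # -- force-velocity -----------------------------------------------------
    def _fv_raw(self, vn):
        d1, d2, d3, d4 = self.fv_d
        x = d2 * np.asarray(vn, dtype=float) + d3
        return d1 * np.log(x + np.sqrt(x**2 + 1.0)) + d4

    def fv(self, v_norm):
        """Force-velocity multiplier; fv(0) == 1 exactly.

        ``v_norm`` is fiber velocity / (v_max * l_opt), lengthening positive.
        """
        return self._fv_raw(v_norm) / self._fv_raw(0.0)

    def dfv(self, v_norm):
        d1, d2, _, _ = self.fv_d
        x = d2 * np.asarray(v_norm, dtype=float) + self.fv_d[2]
        return d1 * d2 / np.sqrt(x**2 + 1.0) / self._fv_raw(0.0)

    def d2fv(self, v_norm):
        d1, d2, _, _ = self.fv_d
        x = d2 * np.asarray(v_norm, dtype=float) + self.fv_d[2]
        return -d1 * d2**2 * x / (x**2 + 1.0) ** 1.5 / self._fv_raw(0.0)

    # -- passive force-length -----------------------------------------------
    @property
    def _fp_k(self) -> float:
        return math.log(1.0 / self.fp_at_optimal) / self.passive_strain_iso

    def fp(self, l_norm):
        """Passive force-length multiplier: positive, strictly increasing."""
        return self.fp_at_optimal * np.exp(self._fp_k * (np.asarray(l_norm, float) - 1.0))

    def dfp(self, l_norm):
        return self._fp_k * self.fp(l_norm)

    # -- tendon force-strain ------------------------------------------------
    def ft(self, strain):
        """Tendon force multiplier vs strain; ft(tendon_strain_iso) == 1."""
        k = self.tendon_k
        c = math.expm1(k * self.tendon_strain_iso)
        return np.expm1(k * np.asarray(strain, dtype=float)) / c

    def dft(self, strain):
        k = self.tendon_k
        c = math.expm1(k * self.tendon_strain_iso)
        return k * np.exp(k * np.asarray(strain, dtype=float)) / c


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class SegmentParams:
    """Rigid-segment inertial parameters (sagittal plane).

    ``com_offset`` is the distance of the mass center from the proximal
    joint along the segment axis; ``inertia_z`` is about the mass center,
    about the medio-lateral axis.
    """

    name: str
    mass: float
    length: float
    com_offset: float
    inertia_z: float

    def validate(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"segment {self.name}: mass must be > 0, got {self.mass}")
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0, got {self.length}")
        if not (0.0 <= self.com_offset <= self.length):
            raise ValueError(
                f"segment {self.name}: com_offset {self.com_offset} outside [0, length]"
            )
        if self.inertia_z < 0:
            raise ValueError(f"segment {self.name}: inertia_z must be >= 0")


@dataclass
class MTUParams:
    """Parameters of one muscle-tendon unit.

    ``moment_arm_coeffs`` maps DOF name -> polynomial coefficients in
    ascending order, giving the moment arm in meters as a function of the
    joint angle in radians.  ``insertion_distance`` is the distance from the
    knee joint center to the MTU's effective attachment along the long axis
    of the adjacent segment; it defines the line-of-action angle used in the
    joint-reaction assembly (knee-crossing units only).
    """

    name: str
    f_max: float
    l_opt: float
    l_slack: float
    pennation_opt: float = 0.0
    tau_act: float = 0.010
    tau_deact: float = 0.040
    rigid_tendon: bool = False
    moment_arm_coeffs: dict[str, list[float]] = field(default_factory=dict)
    insertion_distance: float | None = None

    def validate(self) -> None:
        if self.f_max <= 0:
            raise ValueError(f"MTU {self.name}: f_max must be > 0")
        if self.l_opt <= 0:
            raise ValueError(f"MTU {self.name}: l_opt must be > 0")
        if self.l_slack < 0:
            raise ValueError(f"MTU {self.name}: l_slack must be >= 0")
        if not (0.0 <= self.pennation_opt < math.pi / 2):
            raise ValueError(f"MTU {self.name}: pennation_opt outside [0, pi/2)")
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError(f"MTU {self.name}: time constants must be > 0")
        if not self.moment_arm_coeffs:
            raise ValueError(f"MTU {self.name}: spans no DOF")


@dataclass
class ActuatorParams:
    """Idealized reserve (torque) or residual (force) actuator.

    The control is dimensionless in [-1, 1]; output = control * capacity.
    Residual actuators model the unmeasured saddle-pelvis interaction and
    attach only to pelvis DOFs; together they can support one body weight.
    """

    name: str
    kind: str  # "reserve_torque" | "residual_force"
    dof: str
    capacity: float

    def validate(self) -> None:
        if self.kind not in ("reserve_torque", "residual_force"):
            raise ValueError(f"actuator {self.name}: unknown kind {self.kind!r}")
        if self.capacity <= 0:
            raise ValueError(f"actuator {self.name}: capacity must be > 0")
        if self.kind == "residual_force" and not self.dof.startswith("pelvis"):
            raise ValueError(
                f"actuator {self.name}: residual actuators attach only to pelvis DOFs"
            )


@dataclass
class MusculoskeletalModel:
    """Complete planar model: segments, DOFs, MTUs, actuators, curves."""

    segments: dict[str, SegmentParams]
    dofs: tuple[str, ...]
    mtus: list[MTUParams]
    actuators: list[ActuatorParams]
    hill_curves: HillCurves
    body_mass: float
    gravity: float = GRAVITY
    ref_height: float = 1.75
    ref_mass: float = 75.0
    height: float = 1.75
    #: posture (rad per DOF) at which every MTU sits exactly at
    #: l_slack + l_opt*cos(pennation_opt)
    reference_posture: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for seg in self.segments.values():
            seg.validate()
        for mtu in self.mtus:
            mtu.validate()
            for dof in mtu.moment_arm_coeffs:
                if dof not in self.dofs:
                    raise ValueError(
                        f"MTU {mtu.name}: moment arm references unknown DOF {dof!r}"
                    )
            expected = mtu.l_slack < mtu.l_opt
            if mtu.rigid_tendon != expected:
                raise ValueError(
                    f"MTU {mtu.name}: rigid_tendon={mtu.rigid_tendon} violates the "
                    f"rigid-tendon rule (l_slack={mtu.l_slack} vs l_opt={mtu.l_opt})"
                )
        for act in self.actuators:
            act.validate()
            if act.dof not in self.dofs:
                raise ValueError(f"actuator {act.name}: unknown DOF {act.dof!r}")
        for side in ("r", "l"):
            n = len(self.mtus_for_leg(side))
            if n != 16:
                raise ValueError(f"expected 16 MTUs for leg {side!r}, found {n}")

    # convenience lookups ---------------------------------------------------
    def mtu(self, name: str) -> MTUParams:
        for m in self.mtus:
            if m.name == name:
                return m
        raise KeyError(name)

    def mtus_for_leg(self, side: str) -> list[MTUParams]:
        return [m for m in self.mtus if m.name.endswith(f"_{side}")]

    def actuators_for_dof(self, dof: str) -> list[ActuatorParams]:
        return [a for a in self.actuators if a.dof == dof]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def assign_tendon_rigidity(mtu: MTUParams) -> MTUParams:
    """Apply the rigid-tendon rule.

    The tendon is modeled as rigid exactly when its slack length is strictly
    shorter than the optimal fiber length; a tie is treated as compliant.
    """
    if mtu.l_opt <= 0:
        raise ValueError(f"MTU {mtu.name}: l_opt must be > 0")
    return replace(mtu, rigid_tendon=bool(mtu.l_slack < mtu.l_opt))


def moment_arm(mtu: MTUParams, dof: str, q) -> np.ndarray | float:
    """Moment arm (m) of ``mtu`` about ``dof`` at joint angle(s) ``q`` (rad)."""
    try:
        coeffs = mtu.moment_arm_coeffs[dof]
    except KeyError:
        raise KeyError(f"MTU {mtu.name} has no moment arm about DOF {dof!r}") from None
    return np.polynomial.polynomial.polyval(np.asarray(q, dtype=float), coeffs)


def _excursion_integral(coeffs, q0: float, q) -> np.ndarray | float:
    """Integral of the moment-arm polynomial from q0 to q (closed form)."""
    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q)
    for n, c in enumerate(coeffs):
        out = out + c * (q ** (n + 1) - q0 ** (n + 1)) / (n + 1)
    return out


def mtu_length(
    mtu: MTUParams, q: dict[str, float | np.ndarray], reference_posture: dict[str, float]
) -> np.ndarray | float:
    """MTU path length (m) at posture ``q`` via tendon excursion.

    length = l_slack + l_opt*cos(pennation) - sum over spanned DOFs of the
    integral of the moment arm from the reference posture to ``q``.  This
    guarantees r = -dL/dq exactly.
    """
    length = mtu.l_slack + mtu.l_opt * math.cos(mtu.pennation_opt)
    for dof, coeffs in mtu.moment_arm_coeffs.items():
        if dof not in q:
            raise KeyError(f"MTU {mtu.name}: posture missing DOF {dof!r}")
        q0 = reference_posture.get(dof, 0.0)
        length = length - _excursion_integral(coeffs, q0, q[dof])
    return length


def fiber_force(a, l_norm, v_norm, mtu: MTUParams, curves: HillCurves):
    """Active and passive fiber force along the tendon (N).

    ``l_norm`` and ``v_norm`` are fiber length / l_opt and fiber velocity /
    (v_max * l_opt).  Pennation is held at its optimal-fiber value.
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0) or np.any(a_arr > 1):
        raise ValueError(f"MTU {mtu.name}: activation outside [0, 1]")
    cosp = math.cos(mtu.pennation_opt)
    active = a_arr * curves.fl(l_norm) * curves.fv(v_norm) * mtu.f_max * cosp
    passive = curves.fp(l_norm) * mtu.f_max * cosp
    return active, passive


#: logistic steepness of the activation/deactivation blend (1/activation)
_ACT_BLEND_K = 20.0


def activation_rate(e, a, mtu: MTUParams):
    """First-order activation dynamics da/dt (1/s), smooth at e == a.

    The rate constant blends smoothly between 1/tau_act (excitation above
    activation) and 1/tau_deact (below), via a logistic in (e - a).
    """
    e = np.asarray(e, dtype=float)
    a = np.asarray(a, dtype=float)
    d = e - a
    s = 1.0 / (1.0 + np.exp(-_ACT_BLEND_K * d))
    rate_const = 1.0 / mtu.tau_deact + (1.0 / mtu.tau_act - 1.0 / mtu.tau_deact) * s
    return d * rate_const


def activation_rate_partials(e, a, mtu: MTUParams):
    """(d rate/d e, d rate/d a) of :func:`activation_rate`."""
    e = np.asarray(e, dtype=float)
    a = np.asarray(a, dtype=float)
    d = e - a
    s = 1.0 / (1.0 + np.exp(-_ACT_BLEND_K * d))
    c_d = 1.0 / mtu.tau_deact
    c_a = 1.0 / mtu.tau_act
    rate_const = c_d + (c_a - c_d) * s
    ds = _ACT_BLEND_K * s * (1.0 - s)
    dd = rate_const + d * (c_a - c_d) * ds
    return dd, -dd


def pennation_cos(l_fiber_norm, pennation_opt: float):
    """cos(pennation) under the constant-thickness assumption."""
    sin0 = math.sin(pennation_opt)
    l = np.asarray(l_fiber_norm, dtype=float)
    return np.sqrt(np.maximum(l**2 - sin0**2, 1e-12)) / l


def tendon_length(l_mtu, l_fiber_norm, mtu: MTUParams):
    """Tendon length given MTU length and normalized fiber length."""
    sin0 = math.sin(mtu.pennation_opt)
    l = np.asarray(l_fiber_norm, dtype=float)
    return np.asarray(l_mtu, float) - mtu.l_opt * np.sqrt(np.maximum(l**2 - sin0**2, 1e-12))


def tendon_equilibrium_residual(
    a, l_fiber_norm, v_fiber_norm, l_mtu, mtu: MTUParams, curves: HillCurves
):
    """Force-balance residual (N) of a compliant-tendon MTU.

    residual = tendon force - fiber force projected along the tendon, where
    the fiber force includes the active element, the passive curve, and a
    small parallel damper (``curves.fiber_damping`` x normalized velocity).
    Zero at equilibrium; the redundancy solver drives this to zero through
    the implicit auxiliary dynamics.
    """
    if mtu.rigid_tendon:
        raise ValueError(f"MTU {mtu.name}: tendon equilibrium is undefined for a rigid tendon")
    strain = tendon_length(l_mtu, l_fiber_norm, mtu) / mtu.l_slack - 1.0
    f_tendon = curves.ft(strain) * mtu.f_max
    cosp = pennation_cos(l_fiber_norm, mtu.pennation_opt)
    a_arr = np.asarray(a, dtype=float)
    f_fiber = (
        a_arr * curves.fl(l_fiber_norm) * curves.fv(v_fiber_norm)
        + curves.fp(l_fiber_norm)
        + curves.fiber_damping * np.asarray(v_fiber_norm, dtype=float)
    ) * mtu.f_max * cosp
    return f_tendon - f_fiber


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


def scale_model(generic: MusculoskeletalModel, height: float, mass: float) -> MusculoskeletalModel:
    """Parametric anthropometric scaling of a generic model.

    Lengths (segments, COM offsets, optimal fiber and tendon slack lengths,
    moment arms, insertion distances) scale with the height ratio; masses
    with the mass ratio; inertias with mass ratio x height ratio squared.
    Maximum isometric forces are unchanged.  Residual capacities are re-sized
    to the new body weight.
    """
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be > 0")
    hr = height / generic.ref_height
    mr = mass / generic.ref_mass

    model = copy.deepcopy(generic)
    model.height = height
    model.body_mass = mass
    for seg in model.segments.values():
        seg.length *= hr
        seg.com_offset *= hr
        seg.mass *= mr
        seg.inertia_z *= mr * hr**2
    for mtu in model.mtus:
        mtu.l_opt *= hr
        mtu.l_slack *= hr
        mtu.moment_arm_coeffs = {
            dof: [c * hr for c in coeffs] for dof, coeffs in mtu.moment_arm_coeffs.items()
        }
        if mtu.insertion_distance is not None:
            mtu.insertion_distance *= hr
    bw_ratio = mass * model.gravity / (generic.ref_mass * generic.gravity)
    for act in model.actuators:
        if act.kind == "residual_force":
            act.capacity *= bw_ratio
    return model


# ---------------------------------------------------------------------------
# Default model
# ---------------------------------------------------------------------------

# Per-muscle parameters for the generic 1.75 m / 75 kg model.  Values are
# independent, literature-scale choices for an adult lower limb (isometric
# strengths and fiber/tendon lengths of the familiar lower-extremity
# modeling tradition; moment-arm polynomials are low-order fits to published
# anatomical ranges, in the flexion-positive sign convention).
# Fields: f_max (N), l_opt (m), l_slack (m), pennation (deg),
#         {dof: ascending poly coeffs}, knee insertion distance (m) or None.
_MUSCLE_TABLE: dict[str, tuple] = {
    "glut_max": (1950.0, 0.145, 0.127, 0.0, {"hip": [-0.062, 0.010]}, None),
    "glut_med": (1600.0, 0.073, 0.066, 8.0, {"hip": [-0.025, 0.005]}, None),
    "iliacus": (1070.0, 0.100, 0.090, 7.0, {"hip": [0.035, -0.005]}, None),
    "psoas": (1110.0, 0.104, 0.130, 8.0, {"hip": [0.033, -0.005]}, None),
    "rect_fem": (
        1170.0, 0.076, 0.310, 5.0,
        {"hip": [0.042, -0.008], "knee": [-0.04026, -0.02329, 0.02953, -0.00677]}, 0.120,
    ),
    "vas_lat": (1870.0, 0.099, 0.130, 5.0, {"knee": [-0.04026, -0.02329, 0.02953, -0.00677]}, 0.120),
    "vas_med": (1290.0, 0.089, 0.126, 5.0, {"knee": [-0.04026, -0.02329, 0.02953, -0.00677]}, 0.120),
    "vas_int": (1240.0, 0.087, 0.136, 3.0, {"knee": [-0.04026, -0.02329, 0.02953, -0.00677]}, 0.120),
    "bifemlh": (
        900.0, 0.109, 0.326, 0.0,
        {"hip": [-0.060, 0.006], "knee": [0.030, 0.012, -0.006]}, 0.100,
    ),
    "bifemsh": (800.0, 0.173, 0.089, 23.0, {"knee": [0.030, 0.012, -0.006]}, 0.100),
    "semimem": (
        1300.0, 0.080, 0.335, 15.0,
        {"hip": [-0.055, 0.006], "knee": [0.036, 0.010, -0.006]}, 0.105,
    ),
    "semiten": (
        410.0, 0.201, 0.262, 5.0,
        {"hip": [-0.050, 0.006], "knee": [0.040, 0.012, -0.007]}, 0.120,
    ),
    "med_gas": (
        1560.0, 0.060, 0.390, 17.0,
        {"knee": [0.021, -0.003], "ankle": [-0.054, 0.005]}, 0.055,
    ),
    "lat_gas": (
        680.0, 0.064, 0.385, 8.0,
        {"knee": [0.020, -0.003], "ankle": [-0.053, 0.005]}, 0.055,
    ),
    "soleus": (3550.0, 0.055, 0.250, 25.0, {"ankle": [-0.046, 0.004]}, None),
    "tib_ant": (900.0, 0.098, 0.223, 5.0, {"ankle": [0.040]}, None),
}

KNEE_EXTENSORS = ("rect_fem", "vas_lat", "vas_med", "vas_int")
KNEE_FLEXORS = ("bifemlh", "bifemsh", "semimem", "semiten", "med_gas", "lat_gas")

# Winter-style anthropometric fractions (of height H / total mass M).
_SEG_FRAC = {
    # name: (mass frac, length frac, com frac of length, radius-of-gyration frac)
    "thigh": (0.1000, 0.245, 0.433, 0.323),
    "shank": (0.0465, 0.246, 0.433, 0.302),
    "foot": (0.0145, 0.0835, 0.500, 0.475),  # length = ankle-to-pedal-spindle lever
}

#: reference posture (rad): mid-range seated-cycling configuration at which
#: every MTU is defined to sit at its slack/optimal length
_REFERENCE_POSTURE = {"hip_flexion": 0.9, "knee_flexion": 1.3, "ankle_dorsiflexion": 0.0}

_DOF_SHORT = {"hip": "hip_flexion", "knee": "knee_flexion", "ankle": "ankle_dorsiflexion"}


def generic_model(curves: HillCurves | None = None) -> MusculoskeletalModel:
    """Build the generic (reference anthropometry, 1.75 m / 75 kg) model."""
    curves = curves or HillCurves()
    H, M = 1.75, 75.0
    segments: dict[str, SegmentParams] = {}
    leg_mass = 0.0
    for side in ("r", "l"):
        for name, (mf, lf, cf, kf) in _SEG_FRAC.items():
            L = lf * H
            m = mf * M
            segments[f"{name}_{side}"] = SegmentParams(
                name=f"{name}_{side}",
                mass=m,
                length=L,
                com_offset=cf * L,
                inertia_z=m * (kf * L) ** 2,
            )
            leg_mass += m
    # pelvis segment lumps the torso (seated, quasi-static)
    segments["pelvis"] = SegmentParams(
        name="pelvis", mass=M - leg_mass, length=0.10 * H, com_offset=0.05 * H,
        inertia_z=(M - leg_mass) * (0.15 * H) ** 2,
    )

    dofs = PELVIS_DOFS + leg_dof_names("r") + leg_dof_names("l")

    mtus: list[MTUParams] = []
    for side in ("r", "l"):
        for name, (f_max, l_opt, l_slack, penn_deg, arms, d_ins) in _MUSCLE_TABLE.items():
            coeffs = {
                f"{_DOF_SHORT[short]}_{side}": list(poly) for short, poly in arms.items()
            }
            mtu = MTUParams(
                name=f"{name}_{side}",
                f_max=f_max,
                l_opt=l_opt,
                l_slack=l_slack,
                pennation_opt=math.radians(penn_deg),
                moment_arm_coeffs=coeffs,
                insertion_distance=d_ins,
            )
            mtus.append(assign_tendon_rigidity(mtu))

    bw = M * GRAVITY
    actuators = [
        ActuatorParams("residual_pelvis_x", "residual_force", "pelvis_x", 0.5 * bw),
        ActuatorParams("residual_pelvis_y", "residual_force", "pelvis_y", 1.0 * bw),
        ActuatorParams("residual_pelvis_tilt", "residual_force", "pelvis_tilt", 0.5 * bw),
    ]
    for side in ("r", "l"):
        for dof in leg_dof_names(side):
            # capacity sized so that even a railed reserve stays within the
            # 5%-of-peak-net-moment quality bound at the lowest cohort power
            actuators.append(ActuatorParams(f"reserve_{dof}", "reserve_torque", dof, 0.5))

    reference_posture = {
        f"{full}_{side}": _REFERENCE_POSTURE[full]
        for side in ("r", "l")
        for full in _DOF_SHORT.values()
    }

    model = MusculoskeletalModel(
        segments=segments,
        dofs=dofs,
        mtus=mtus,
        actuators=actuators,
        hill_curves=curves,
        body_mass=M,
        height=H,
        reference_posture=reference_posture,
    )
    model.validate()
    return model


def default_model(height: float = 1.75, mass: float = 75.0) -> MusculoskeletalModel:
    """Generic model scaled to the given stature (m) and body mass (kg)."""
    return scale_model(generic_model(), height, mass)
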