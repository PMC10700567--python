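"""Newton-Euler inverse dynamics of the planar leg chain.

Net joint moments (hip flexion, knee flexion, ankle dorsiflexion positive)
and intersegmental joint forces are computed distal-to-proximal from the
trial kinematics and pedal loads.  The pelvis balance is closed by an
explicit saddle reaction (the residual demand), so that a dynamically
consistent trial needs no residual actuation beyond the saddle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import CrankGeometry, TrialKinematics, pedal_tangent, segment_revolutions
from .model import MusculoskeletalModel


@dataclass
class PedalLoad:
    """Pedal load of one leg, lab frame, on the trial time grid.

    Drive convention: (fx, fy) is the force the foot applies to the pedal,
    as instrumented pedals and power meters report it; the reaction -F acts
    on the foot in the inverse-dynamics recursion.  (px, py) is the
    application point (pedal spindle)."""

    time: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    px: np.ndarray
    py: np.ndarray
    free_moment: np.ndarray | None = None

    def validate(self) -> None:
        n = len(self.time)
        for name in ("fx", "fy", "px", "py"):
            v = getattr(self, name)
            if len(v) != n:
                raise ValueError(f"pedal load column {name} length mismatch")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"pedal load column {name} contains non-finite values")


@dataclass
class NetMoments:
    """Net joint moments (N*m) per DOF over the trial grid."""

    time: np.ndarray
    moments: dict[str, np.ndarray]  # dof name -> series

    def __getitem__(self, dof: str) -> np.ndarray:
        return self.moments[dof]


@dataclass
class IntersegmentalLoads:
    """Muscle-free joint reaction forces of the skeletal recursion (lab frame).

    ``on_distal[joint]`` is the force the proximal segment applies to the
    distal segment at that joint; action-reaction gives the converse.
    ``axial_knee`` is the component of the knee force on the tibia along the
    distal (ankle-ward) tibial axis: positive = compression.
    """

    time: np.ndarray
    on_distal: dict[str, np.ndarray]  # joint -> (n, 2)
    axial_knee: np.ndarray = field(default=None)


def _chain_points(kin: TrialKinematics, geom: CrankGeometry,
                  model: MusculoskeletalModel, side: str):
    """Positions/accelerations of joints and segment mass centers."""
    alpha = kin.angles[f"hip_flexion_{side}"]
    dalpha = kin.velocities[f"hip_flexion_{side}"]
    ddalpha = kin.accelerations[f"hip_flexion_{side}"]
    qk = kin.angles[f"knee_flexion_{side}"]
    dqk = kin.velocities[f"knee_flexion_{side}"]
    ddqk = kin.accelerations[f"knee_flexion_{side}"]
    qa = kin.angles[f"ankle_dorsiflexion_{side}"]
    dqa = kin.velocities[f"ankle_dorsiflexion_{side}"]
    ddqa = kin.accelerations[f"ankle_dorsiflexion_{side}"]

    beta, dbeta, ddbeta = alpha - qk, dalpha - dqk, ddalpha - ddqk
    psi, dpsi, ddpsi = beta + qa, dbeta + dqa, ddbeta + ddqa

    thigh = model.segments[f"thigh_{side}"]
    shank = model.segments[f"shank_{side}"]
    foot = model.segments[f"foot_{side}"]
    hx, hy = geom.saddle_position

    def point_u(base, L, phi, dphi, ddphi):
        # base: (pos, vel, acc) tuples of arrays; direction u(phi)=(sin,-cos)
        s, c = np.sin(phi), np.cos(phi)
        pos = (base[0][0] + L * s, base[0][1] - L * c)
        vel = (base[1][0] + L * c * dphi, base[1][1] + L * s * dphi)
        acc = (
            base[2][0] + L * (c * ddphi - s * dphi**2),
            base[2][1] + L * (s * ddphi + c * dphi**2),
        )
        return pos, vel, acc

    def point_w(base, L, phi, dphi, ddphi):
        # direction w(phi) = (cos, sin)
        s, c = np.sin(phi), np.cos(phi)
        pos = (base[0][0] + L * c, base[0][1] + L * s)
        vel = (base[1][0] - L * s * dphi, base[1][1] + L * c * dphi)
        acc = (
            base[2][0] - L * (s * ddphi + c * dphi**2),
            base[2][1] + L * (c * ddphi - s * dphi**2),
        )
        return pos, vel, acc

    zero = np.zeros_like(alpha)
    hip = ((hx + zero, hy + zero), (zero, zero), (zero, zero))
    knee = point_u(hip, thigh.length, alpha, dalpha, ddalpha)
    com_t = point_u(hip, thigh.com_offset, alpha, dalpha, ddalpha)
    ankle = point_u(knee, shank.length, beta, dbeta, ddbeta)
    com_s = point_u(knee, shank.com_offset, beta, dbeta, ddbeta)
    pedal = point_w(ankle, foot.length, psi, dpsi, ddpsi)
    com_f = point_w(ankle, foot.com_offset, psi, dpsi, ddpsi)

    return {
        "hip": hip, "knee": knee, "ankle": ankle, "pedal": pedal,
        "com_thigh": com_t, "com_shank": com_s, "com_foot": com_f,
        "beta": (beta, dbeta, ddbeta), "psi": (psi, dpsi, ddpsi),
        "alpha": (alpha, dalpha, ddalpha),
    }


def _cross(rx, ry, fx, fy):
    return rx * fy - ry * fx


def net_joint_moments(kin: TrialKinematics, load: PedalLoad,
                      model: MusculoskeletalModel, geom: CrankGeometry,
                      side: str = "r") -> tuple[NetMoments, IntersegmentalLoads]:
    """Distal-to-proximal Newton-Euler recursion for one leg.

    At every sample each joint moment balances the segment inertial,
    gravitational, and external (pedal) terms.  Returns the net moments in
    the flexion/flexion/dorsiflexion-positive convention plus the
    muscle-free intersegmental loads used by the joint-reaction assembly.
    """
    if len(load.time) != len(kin.time) or not np.allclose(load.time, kin.time):
        raise ValueError("pedal load and kinematics are on different time grids")
    load.validate()

    pts = _chain_points(kin, geom, model, side)
    g = model.gravity
    thigh = model.segments[f"thigh_{side}"]
    shank = model.segments[f"shank_{side}"]
    foot = model.segments[f"foot_{side}"]

    fpx, fpy = load.fx, load.fy
    apx, apy = load.px, load.py
    free_m = load.free_moment if load.free_moment is not None else 0.0

    # foot
    cfx, cfy = pts["com_foot"][0]
    afx, afy = pts["com_foot"][2]
    ax_, ay_ = pts["ankle"][0]
    ddpsi = pts["psi"][2]
    # reaction on the foot is -(fpx, fpy)
    F_ank_x = foot.mass * afx + fpx
    F_ank_y = foot.mass * afy + foot.mass * g + fpy
    M_ank = (
        foot.inertia_z * ddpsi
        - _cross(ax_ - cfx, ay_ - cfy, F_ank_x, F_ank_y)
        + _cross(apx - cfx, apy - cfy, fpx, fpy)
        + free_m
    )

    # shank
    csx, csy = pts["com_shank"][0]
    asx, asy = pts["com_shank"][2]
    kx_, ky_ = pts["knee"][0]
    ddbeta = pts["beta"][2]
    F_kne_x = shank.mass * asx + F_ank_x
    F_kne_y = shank.mass * asy + shank.mass * g + F_ank_y
    M_kne = (
        shank.inertia_z * ddbeta
        + M_ank
        - _cross(kx_ - csx, ky_ - csy, F_kne_x, F_kne_y)
        + _cross(ax_ - csx, ay_ - csy, F_ank_x, F_ank_y)
    )

    # thigh
    ctx, cty = pts["com_thigh"][0]
    atx, aty = pts["com_thigh"][2]
    hx_, hy_ = pts["hip"][0]
    ddalpha = pts["alpha"][2]
    F_hip_x = thigh.mass * atx + F_kne_x
    F_hip_y = thigh.mass * aty + thigh.mass * g + F_kne_y
    M_hip = (
        thigh.inertia_z * ddalpha
        + M_kne
        - _cross(hx_ - ctx, hy_ - cty, F_hip_x, F_hip_y)
        + _cross(kx_ - ctx, ky_ - cty, F_kne_x, F_kne_y)
    )

    moments = NetMoments(
        time=kin.time,
        moments={
            f"hip_flexion_{side}": M_hip,
            f"knee_flexion_{side}": -M_kne,
            f"ankle_dorsiflexion_{side}": M_ank,
        },
    )
    # knee force on tibia along the distal tibial axis = compression
    beta = pts["beta"][0]
    ux, uy = np.sin(beta), -np.cos(beta)
    axial = F_kne_x * ux + F_kne_y * uy
    inter = IntersegmentalLoads(
        time=kin.time,
        on_distal={
            "ankle": np.column_stack([F_ank_x, F_ank_y]),
            "knee": np.column_stack([F_kne_x, F_kne_y]),
            "hip": np.column_stack([F_hip_x, F_hip_y]),
        },
        axial_knee=axial,
    )
    return moments, inter


def pedal_force_check(kin, model: MusculoskeletalModel, geom, inter: IntersegmentalLoads,
                      side: str = "r"):
    """Forward free-body check: re-derive the (drive-convention) pedal force
    from the returned ankle intersegmental force; used to assert consistency
    to ~1e-6 N."""
    pts = _chain_points(kin, geom, model, side)
    foot = model.segments[f"foot_{side}"]
    afx, afy = pts["com_foot"][2]
    F_ank = inter.on_distal["ankle"]
    fpx = F_ank[:, 0] - foot.mass * afx
    fpy = F_ank[:, 1] - foot.mass * afy - foot.mass * model.gravity
    return fpx, fpy


def saddle_closure(kin: TrialKinematics, loads: dict[str, PedalLoad],
                   model: MusculoskeletalModel, geom: CrankGeometry):
    """Saddle reaction (Fx, Fy, Mz) that exactly balances the pelvis.

    The pelvis (which lumps the torso) is stationary; the saddle reaction is
    the closure of the Newton-Euler balance given both legs' hip loads.
    Returns (fx, fy, mz) series; a trial that stores these is dynamically
    consistent by construction (zero residual demand beyond the saddle).
    """
    pelvis = model.segments["pelvis"]
    g = model.gravity
    fx = np.full(len(kin.time), 0.0)
    fy = np.full(len(kin.time), pelvis.mass * g)
    mz = np.zeros(len(kin.time))
    for side, load in loads.items():
        m, inter = net_joint_moments(kin, load, model, geom, side=side)
        F_hip = inter.on_distal["hip"]
        fx += F_hip[:, 0]
        fy += F_hip[:, 1]
        # hip joints coincide at the saddle point in the planar model, so
        # the force transmits with no extra lever; tilt closure collects the
        # hip flexion moments' reactions.
        mz += m[f"hip_flexion_{side}"]
    return fx, fy, mz


def crank_power(loads, crank_angle, geom: CrankGeometry, time=None) -> float:
    """Mean crank power (W) over complete revolutions.

    ``loads`` is one PedalLoad or a list (one per instrumented leg); power
    is the tangential pedal force times crank length times crank angular
    velocity, averaged TDC-to-TDC and summed over legs.
    """
    if isinstance(loads, PedalLoad):
        loads = [loads]
    th = np.asarray(crank_angle, dtype=float)
    windows = segment_revolutions(th)  # raises if < 1 revolution
    t = np.asarray(time if time is not None else loads[0].time, dtype=float)
    omega = np.gradient(th, t)
    total = 0.0
    for k, load in enumerate(loads):
        # the left crank is offset by pi from the stored (right-leg) angle,
        # but tangential direction depends on each leg's own crank angle
        th_leg = th if k == 0 else th + np.pi
        tx, ty = pedal_tangent(th_leg)
        f_tan = load.fx * tx + load.fy * ty
        p = f_tan * geom.crank_length * omega
        vals = []
        for i0, i1 in windows:
            vals.append(np.trapezoid(p[i0 : i1 + 1], t[i0 : i1 + 1]) / (t[i1] - t[i0]))
        total += float(np.mean(vals))
    return total


def joint_power_work(kin: TrialKinematics, moments: NetMoments, window, side: str = "r"):
    """Integral of sum(M_dof * qdot_dof) over a revolution window (J)."""
    i0, i1 = window
    t = kin.time[i0 : i1 + 1]
    p = np.zeros_like(t)
    for dof in (f"hip_flexion_{side}", f"knee_flexion_{side}", f"ankle_dorsiflexion_{side}"):
        p += moments[dof][i0 : i1 + 1] * kin.velocities[dof][i0 : i1 + 1]
    return float(np.trapezoid(p, t))
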