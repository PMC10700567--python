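"""Tibiofemoral joint-reaction assembly and peak detection.

The compressive tibiofemoral force is the free-body sum over the isolated
tibia: the axial (superior-inferior, along the tibial long axis) component
of the muscle-free intersegmental knee force, plus every knee-crossing
MTU's total force projected onto the tibial axis.  Each knee-crossing MTU
carries an effective insertion distance d from the knee center; its line
of action passes the knee at the moment-arm distance r, so the angle to
the tibial axis satisfies sin(phi) = |r|/d and the compressive direction
cosine is cos(phi) = sqrt(1 - (r/d)^2) >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import IntersegmentalLoads
from .kinematics import TrialKinematics
from .model import MusculoskeletalModel, moment_arm
from .solver import RedundancySolution

TWO_PI = 2.0 * np.pi


@dataclass
class JointReactionTrajectory:
    """Compressive tibiofemoral force (N, positive = compression) over the
    solution grid, with the crank angle of every sample."""

    time: np.ndarray
    crank_angle: np.ndarray  # rad, 0 at TDC
    force: np.ndarray
    side: str = "r"

    def analyzed(self, grid):
        sl = grid.analyzed
        return self.crank_angle[sl], self.force[sl]


@dataclass
class PeakReport:
    """First (just after TDC) and second (before BDC) compressive peaks."""

    first_force: float | None
    first_angle: float | None  # rad
    second_force: float | None
    second_angle: float | None


def knee_direction_cosine(mtu, q_knee, dof: str):
    """Compressive direction cosine of a knee-crossing MTU at posture(s)."""
    r = np.abs(np.asarray(moment_arm(mtu, dof, q_knee)))
    if not mtu.insertion_distance:
        raise ValueError(f"MTU {mtu.name} carries no insertion geometry")
    sinphi = np.clip(r / mtu.insertion_distance, 0.0, 0.98)
    return np.sqrt(1.0 - sinphi**2)


def tibiofemoral_force(solution: RedundancySolution, kin: TrialKinematics,
                       inter: IntersegmentalLoads, model: MusculoskeletalModel,
                       side: str = "r") -> JointReactionTrajectory:
    """Assemble the compressive tibiofemoral force of one leg.

    Uses each knee-crossing MTU's total (active + passive) force from the
    redundancy solution and the muscle-free intersegmental axial component
    interpolated onto the solution grid.
    """
    times = solution.times
    if inter.time.shape != kin.time.shape or not np.allclose(inter.time, kin.time):
        raise ValueError("intersegmental loads and kinematics are on different grids")
    axial = np.interp(times, inter.time, inter.axial_knee)
    force = axial.copy()
    kd = f"knee_flexion_{side}"
    q_knee = kin.angle(kd, times)
    for i, name in enumerate(solution.muscle_names):
        mtu = model.mtu(name)
        if kd not in mtu.moment_arm_coeffs or not mtu.insertion_distance:
            continue
        cosphi = knee_direction_cosine(mtu, q_knee, kd)
        force = force + cosphi * solution.force_total[i]
    crank = kin.crank_angle_at(times)
    return JointReactionTrajectory(time=times, crank_angle=crank, force=force, side=side)


def _quadratic_peak(theta, y, k):
    """Refine a discrete local maximum by quadratic interpolation."""
    if k == 0 or k == len(y) - 1:
        return theta[k], y[k]
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-12:
        return theta[k], y[k]
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    th = theta[k] + delta * (theta[min(k + 1, len(y) - 1)] - theta[k])
    val = y1 - 0.25 * (y0 - y2) * delta
    return th, val


def find_peaks(traj: JointReactionTrajectory, grid=None) -> PeakReport:
    """Locate the characteristic first and second compressive peaks.

    Works on one complete revolution (TDC to TDC).  The first peak is the
    largest local maximum in crank angle (0, 180) deg; the second is the
    largest remaining maximum in (90, 180) deg at a later angle; an absent
    second peak is reported as None, never invented.
    """
    if grid is not None:
        theta, y = traj.analyzed(grid)
    else:
        theta, y = traj.crank_angle, traj.force
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta[-1] - theta[0] < TWO_PI - 1e-6:
        raise ValueError("need one complete revolution")
    if np.ptp(y) < 1e-9:
        return PeakReport(None, None, None, None)

    # local maxima over the (periodic) revolution; flat plateaus are not
    # peaks, and ripples below 1% prominence are ignored
    yp = np.concatenate([[y[-2]], y, [y[1]]])  # periodic padding (endpoints equal)
    floor = y.min() + 0.01 * np.ptp(y)
    cand = []
    for k in range(len(y)):
        if (yp[k + 1] >= yp[k] and yp[k + 1] >= yp[k + 2]
                and (yp[k + 1] > yp[k] or yp[k + 1] > yp[k + 2])
                and yp[k + 1] > floor):
            th, val = _quadratic_peak(theta, y, k)
            cand.append((th - theta[0], val))
    first = None
    for th, val in cand:
        if 0.0 < th < np.pi and (first is None or val > first[1]):
            first = (th, val)
    second = None
    for th, val in cand:
        if first is not None and abs(th - first[0]) < 1e-9:
            continue
        if np.pi / 2 < th < np.pi and (second is None or val > second[1]):
            second = (th, val)
    return PeakReport(
        first_force=None if first is None else first[1],
        first_angle=None if first is None else first[0],
        second_force=None if second is None else second[1],
        second_angle=None if second is None else second[0],
    )
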