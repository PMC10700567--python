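"""Crank/pedal geometry, closed-form leg inverse kinematics, revolution
segmentation, and zero-phase filtering.

Conventions
-----------
Lab frame: x forward, y up, origin at the crank axis unless stated.
Crank angle theta: 0 at right-foot top dead center (TDC, pedal highest),
increasing in the pedaling direction; the left crank leads/lags by pi.
Segment direction u(phi) = (sin phi, -cos phi) points from the proximal to
the distal joint; phi = 0 is straight down, positive rotates the distal end
forward.  With an upright-trunk pelvis convention, the thigh angle equals
hip flexion, the shank angle is hip flexion - knee flexion, and the foot
forward direction is at shank angle + ankle dorsiflexion (neutral foot
perpendicular to the shank).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class AnkleProfile:
    """Smooth periodic ankle-dorsiflexion profile (rad) vs crank angle.

    Two-harmonic Fourier form: mean + a1*cos(theta) + a2*cos(2*theta - p2).
    The positive-cos fundamental makes the ankle most dorsiflexed near TDC
    and most plantarflexed near BDC, the canonical pattern.
    """

    mean: float = -0.10
    a1: float = 0.33
    a2: float = 0.05
    p2: float = 0.0

    def __call__(self, theta):
        th = np.asarray(theta, dtype=float)
        return self.mean + self.a1 * np.cos(th) + self.a2 * np.cos(2.0 * th - self.p2)

    def derivative(self, theta):
        th = np.asarray(theta, dtype=float)
        return -self.a1 * np.sin(th) - 2.0 * self.a2 * np.sin(2.0 * th - self.p2)


@dataclass
class CrankGeometry:
    """Bike-fit geometry: crank, saddle (hip center), and ankle profile."""

    crank_length: float = 0.1725
    crank_axis: tuple[float, float] = (0.0, 0.0)
    saddle_position: tuple[float, float] = (-0.196, 0.682)
    ankle_profile: AnkleProfile = field(default_factory=AnkleProfile)

    def validate(self) -> None:
        if self.crank_length <= 0:
            raise ValueError("crank_length must be > 0")
        if self.saddle_position[1] <= self.crank_axis[1]:
            raise ValueError("saddle must sit above the crank axis")


#: hip-center distance from crank axis along the seat tube, as a fraction of
#: stature: 0.97 (hip-above-saddle correction) x 0.883 x inseam proxy 0.48 H
_HIP_FRAC = 0.97 * 0.883 * 0.48
_SEAT_TUBE_ANGLE = math.radians(74.0)
#: crank length as a fraction of stature (172.5 mm at the 1.75 m reference),
#: clipped to the commercially common range
_CRANK_FRAC = 0.1725 / 1.75


def recreational_geometry(height: float, crank_length: float | None = None) -> CrankGeometry:
    """Bike fit derived from anthropometrics (documented parametric stand-in
    for a measured fit prescription).  Crank length scales with stature, as
    fitters prescribe, unless given explicitly."""
    if crank_length is None:
        crank_length = min(max(_CRANK_FRAC * height, 0.160), 0.1775)
    d = _HIP_FRAC * height
    saddle = (-d * math.cos(_SEAT_TUBE_ANGLE), d * math.sin(_SEAT_TUBE_ANGLE))
    return CrankGeometry(crank_length=crank_length, saddle_position=saddle)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def dual_pass_butterworth(x, fs: float, fc: float, order: int = 2, padlen: int | None = None):
    """Zero-phase low-pass filter: one forward and one backward pass of a
    Butterworth filter of the given order, with reflective edge padding.

    Each pass contributes -3 dB at ``fc``, so the dual-pass gain at the
    cutoff is 0.5.  Output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if fc >= fs / 2.0:
        raise ValueError(f"cutoff {fc} Hz must be below the Nyquist frequency {fs / 2.0} Hz")
    if x.shape[-1] <= 3 * order:
        raise ValueError(f"series of length {x.shape[-1]} too short for order-{order} filter")
    b, a = butter(order, fc, fs=fs)
    if padlen is None:
        padlen = min(x.shape[-1] - 1, 10 * max(len(a), len(b)))
    else:
        padlen = min(padlen, x.shape[-1] - 1)
    return filtfilt(b, a, x, padlen=padlen)


# ---------------------------------------------------------------------------
# Crank and leg kinematics
# ---------------------------------------------------------------------------


def pedal_position(theta, geom: CrankGeometry):
    """Pedal-spindle position for crank angle(s) ``theta``; theta=0 is TDC."""
    th = np.asarray(theta, dtype=float)
    ax, ay = geom.crank_axis
    return ax + geom.crank_length * np.sin(th), ay + geom.crank_length * np.cos(th)


def pedal_tangent(theta):
    """Unit tangent of the pedal path in the direction of increasing theta."""
    th = np.asarray(theta, dtype=float)
    return np.cos(th), -np.sin(th)


def _seg_u(phi):
    return np.sin(phi), -np.cos(phi)


def forward_kinematics(hip_flexion, knee_flexion, ankle_angle, geom: CrankGeometry,
                       thigh: float, shank: float, foot_lever: float):
    """Pedal-spindle position from joint angles (inverse of the IK)."""
    alpha = np.asarray(hip_flexion, dtype=float)
    beta = alpha - np.asarray(knee_flexion, dtype=float)
    psi = beta + np.asarray(ankle_angle, dtype=float)
    hx, hy = geom.saddle_position
    ux_t, uy_t = _seg_u(alpha)
    ux_s, uy_s = _seg_u(beta)
    px = hx + thigh * ux_t + shank * ux_s + foot_lever * np.cos(psi)
    py = hy + thigh * uy_t + shank * uy_s + foot_lever * np.sin(psi)
    return px, py


class ReachabilityError(ValueError):
    """Pedal target outside the leg's reachable annulus."""


def leg_inverse_kinematics(pedal_xy, ankle_angle, geom: CrankGeometry,
                           thigh: float, shank: float, foot_lever: float,
                           crank_angle=None, tol: float = 1e-14, max_iter: int = 80):
    """Closed-form planar leg IK with a prescribed ankle angle.

    Returns (hip_flexion, knee_flexion) on the anatomically admissible
    branch (knee flexion >= 0).  Because the foot direction depends on the
    shank angle, the two-link solution is wrapped in a fixed-point iteration
    on the shank angle, which converges geometrically (the foot lever is
    short relative to the leg).  Accepts scalars or arrays.
    """
    px = np.atleast_1d(np.asarray(pedal_xy[0], dtype=float))
    py = np.atleast_1d(np.asarray(pedal_xy[1], dtype=float))
    qa = np.broadcast_to(np.asarray(ankle_angle, dtype=float), px.shape).copy()
    hx, hy = geom.saddle_position

    beta = np.arctan2(px - hx, -(py - hy))  # start: shank toward the raw pedal point
    alpha = np.zeros_like(beta)
    qk = np.zeros_like(beta)
    for _ in range(max_iter):
        psi = beta + qa
        tx = px - foot_lever * np.cos(psi) - hx
        ty = py - foot_lever * np.sin(psi) - hy
        d = np.hypot(tx, ty)
        lo, hi = abs(thigh - shank), thigh + shank
        bad = (d <= lo) | (d >= hi)
        if np.any(bad):
            idx = int(np.argmax(bad))
            where = (
                f"crank angle {float(np.degrees(np.atleast_1d(crank_angle)[idx])):.1f} deg"
                if crank_angle is not None
                else f"sample {idx}"
            )
            raise ReachabilityError(
                f"ankle target at distance {d.flat[idx]:.4f} m outside reachable "
                f"annulus ({lo:.4f}, {hi:.4f}) at {where}"
            )
        cos_chi = (thigh**2 + shank**2 - d**2) / (2.0 * thigh * shank)
        chi = np.arccos(np.clip(cos_chi, -1.0, 1.0))
        qk_new = math.pi - chi  # knee flexion >= 0 branch
        phi_d = np.arctan2(tx, -ty)
        cos_delta = (thigh**2 + d**2 - shank**2) / (2.0 * thigh * d)
        delta = np.arccos(np.clip(cos_delta, -1.0, 1.0))
        alpha_new = phi_d + delta  # knee forward of the hip-ankle chord
        beta_new = alpha_new - qk_new
        step = np.max(np.abs(beta_new - beta))
        alpha, qk, beta = alpha_new, qk_new, beta_new
        if step < tol:
            break
    if np.isscalar(pedal_xy[0]) or np.asarray(pedal_xy[0]).ndim == 0:
        return float(alpha[0]), float(qk[0])
    return alpha, qk


# ---------------------------------------------------------------------------
# Revolution segmentation and resampling
# ---------------------------------------------------------------------------


def segment_revolutions(crank_angle) -> list[tuple[int, int]]:
    """TDC-to-TDC windows as (start_idx, end_idx) sample-index pairs.

    A revolution spans crank angle [2*pi*k, 2*pi*(k+1)]; crossings are
    located by linear interpolation and snapped to the nearest sample.
    Windows are contiguous and non-overlapping; partial revolutions at
    either end are excluded.
    """
    th = np.asarray(crank_angle, dtype=float)
    if th.ndim != 1 or len(th) < 2:
        raise ValueError("crank_angle must be a 1-D series")
    if np.any(np.diff(th) <= 0):
        raise ValueError("crank_angle must be strictly increasing")
    k_first = math.ceil(th[0] / TWO_PI - 1e-12)
    k_last = math.floor(th[-1] / TWO_PI + 1e-12)
    if k_last - k_first < 1:
        raise ValueError("series spans less than one complete revolution")
    idx = []
    for k in range(k_first, k_last + 1):
        target = TWO_PI * k
        j = int(np.searchsorted(th, target))
        if j == 0:
            idx.append(0)
            continue
        j = min(j, len(th) - 1)
        # nearest of the two bracketing samples to the interpolated crossing
        frac = (target - th[j - 1]) / (th[j] - th[j - 1])
        idx.append(j - 1 if frac < 0.5 else j)
    return [(idx[i], idx[i + 1]) for i in range(len(idx) - 1)]


PERCENT_CYCLE_GRID = np.linspace(0.0, 100.0, 101)


def resample_percent_cycle(series, crank_angle, window: tuple[int, int]):
    """Resample one revolution of ``series`` to 101 points of % crank cycle
    (0% = TDC, 50% ~ BDC)."""
    i0, i1 = window
    th = np.asarray(crank_angle, dtype=float)[i0 : i1 + 1]
    y = np.asarray(series, dtype=float)[i0 : i1 + 1]
    pct = (th - th[0]) / (th[-1] - th[0]) * 100.0
    return np.interp(PERCENT_CYCLE_GRID, pct, y)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class TimeGrid:
    """Simulation window [t0, tf] with node count and cadence metadata."""

    t0: float
    tf: float
    n_nodes: int
    cadence: float

    def validate(self) -> None:
        if self.tf <= self.t0:
            raise ValueError("tf must exceed t0")
        if self.n_nodes < 11:
            raise ValueError("need at least 11 nodes")
        if (self.tf - self.t0) < 60.0 / self.cadence - 1e-12:
            raise ValueError("window shorter than one revolution")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t0, self.tf, self.n_nodes)


class TrialKinematics:
    """Time series of crank angle and joint kinematics, backed by smooth
    splines so that velocities and accelerations are exact derivatives of the
    (smoothed) joint-angle curves."""

    def __init__(self, time, crank_angle, joint_angles: dict[str, np.ndarray]):
        self.time = np.asarray(time, dtype=float)
        self.crank_angle = np.asarray(crank_angle, dtype=float)
        if np.any(np.diff(self.crank_angle) <= 0):
            raise ValueError("crank_angle must be strictly increasing")
        self._splines = {
            dof: CubicSpline(self.time, np.asarray(q, dtype=float))
            for dof, q in joint_angles.items()
        }
        self.angles = {dof: np.asarray(q, dtype=float).copy() for dof, q in joint_angles.items()}
        self.velocities = {dof: s(self.time, 1) for dof, s in self._splines.items()}
        self.accelerations = {dof: s(self.time, 2) for dof, s in self._splines.items()}

    @property
    def dofs(self) -> tuple[str, ...]:
        return tuple(self.angles.keys())

    def angle(self, dof, t):
        return self._splines[dof](t)

    def velocity(self, dof, t):
        return self._splines[dof](t, 1)

    def acceleration(self, dof, t):
        return self._splines[dof](t, 2)

    def crank_angle_at(self, t):
        return np.interp(t, self.time, self.crank_angle)
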