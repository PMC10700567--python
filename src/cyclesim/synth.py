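"""Synthetic dynamically consistent seated-cycling trials.

The generator emulates the conditions of a 16-participant
recreational cohort (power 40-216 W, cadence 75-92 RPM, height
159.8-195.4 cm, mass 54.2-92.3 kg): crank rotation at constant cadence,
closed-form leg inverse kinematics against an anthropometric bike fit, a
downstroke-dominant pedal-force profile scaled to the target power, the
standard measurement chain (kinematics sampled at 112.5 Hz and low-passed
at 6 Hz; pedal forces at 450 Hz, low-passed at 10 Hz, resampled to the
kinematic grid), and an explicit saddle reaction closing the pelvis
balance, which makes every trial dynamically consistent by construction.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import io as stoio
from .dynamics import PedalLoad, crank_power, saddle_closure
from .kinematics import (
    AnkleProfile,
    CrankGeometry,
    TrialKinematics,
    dual_pass_butterworth,
    forward_kinematics,
    leg_inverse_kinematics,
    pedal_position,
    pedal_tangent,
    recreational_geometry,
)
from .model import MusculoskeletalModel, default_model

TWO_PI = 2.0 * math.pi

# Reference cohort (descriptive statistics of a published recreational
# cycling experiment): (id, height cm, mass kg, sex, cadence RPM,
# power W, age years).
TABLE1_ROWS = [
    ("P01", 169.0, 60.4, "F", 77, 60, 29),
    ("P02", 182.2, 92.3, "M", 80, 107, 22),
    ("P03", 171.2, 74.2, "M", 83, 120, 21),
    ("P04", 166.2, 61.1, "F", 92, 81, 23),
    ("P05", 195.4, 90.8, "M", 84, 136, 28),
    ("P06", 181.7, 77.3, "M", 90, 216, 27),
    ("P07", 188.1, 79.4, "M", 92, 161, 41),
    ("P08", 173.0, 66.5, "M", 90, 117, 42),
    ("P09", 179.8, 76.1, "M", 75, 156, 26),
    ("P10", 183.5, 89.3, "M", 85, 160, 19),
    ("P11", 163.1, 54.2, "F", 78, 94, 32),
    ("P12", 183.7, 91.5, "M", 80, 116, 31),
    ("P13", 191.6, 83.0, "M", 90, 199, 44),
    ("P14", 159.8, 56.7, "F", 86, 40, 42),
    ("P15", 168.5, 57.1, "F", 85, 144, 31),
    ("P16", 179.6, 78.0, "M", 89, 208, 35),
]

KINEMATICS_RATE = 112.5  # Hz
FORCE_RATE = 450.0  # Hz
KINEMATICS_CUTOFF = 6.0  # Hz
FORCE_CUTOFF = 10.0  # Hz


@dataclass
class TrialMeta:
    participant_id: str
    height_m: float
    mass_kg: float
    cadence_rpm: float
    power_w: float
    seed: int
    sex: str = ""
    age: int | None = None


@dataclass
class CohortSpec:
    """Cohort sampling specification (defaults follow the printed cohort)."""

    n_participants: int = 16
    source: str = "table1_rows"  # or "sampled_ranges"
    power_range: tuple[float, float] = (40.0, 216.0)
    cadence_range: tuple[float, float] = (75.0, 92.0)
    height_range: tuple[float, float] = (159.8, 195.4)  # cm
    mass_range: tuple[float, float] = (54.2, 92.3)  # kg
    seed: int = 0


def sample_cohort(spec: CohortSpec) -> list[TrialMeta]:
    """Deterministic cohort metadata; ``table1_rows`` returns the 16 printed
    rows verbatim, ``sampled_ranges`` draws uniformly within the ranges."""
    if spec.n_participants <= 0:
        raise ValueError("n_participants must be > 0")
    metas = []
    if spec.source == "table1_rows":
        for i, (pid, h_cm, m_kg, sex, cad, pw, age) in enumerate(TABLE1_ROWS):
            metas.append(
                TrialMeta(pid, h_cm / 100.0, m_kg, float(cad), float(pw),
                          seed=(spec.seed * 1000 + i) % (2**31 - 1), sex=sex, age=age)
            )
        return metas
    if spec.source != "sampled_ranges":
        raise ValueError(f"unknown cohort source {spec.source!r}")
    rng = np.random.default_rng(spec.seed)
    for i in range(spec.n_participants):
        metas.append(
            TrialMeta(
                f"S{i + 1:02d}",
                rng.uniform(*spec.height_range) / 100.0,
                rng.uniform(*spec.mass_range),
                rng.uniform(*spec.cadence_range),
                rng.uniform(*spec.power_range),
                seed=(spec.seed * 1000 + i) % (2**31 - 1),
            )
        )
    return metas


# ---------------------------------------------------------------------------
# Pedal force profile
# ---------------------------------------------------------------------------


@dataclass
class PedalShape:
    """Shape of the periodic tangential pedal-force profile.

    A raised-cosine burst of the given angular width centered in the
    downstroke, minus a small constant recovery drag.  The power-independent
    radial (along-crank, mechanically ineffective) component follows the
    downward-push pattern of recreational riders: pressing down compresses
    the crank near TDC and extends it near BDC, i.e. radial ~ -cos(theta),
    with a weight-proportional magnitude (~0.22 body weight by default),
    attenuated during the recovery half where the leg partially unweights.
    """

    center: float = math.pi / 2
    width: float = math.radians(170.0)
    recovery: float = 0.06
    radial_peak: float = 162.0  # N (~0.22 BW at the 75 kg reference)
    recovery_weight: float = 0.2  # fraction of the push retained in recovery

    def radial(self, theta):
        th = np.asarray(theta, dtype=float)
        # squared half-sine: ~1 mid-downstroke, ~0.25 at TDC/BDC, 0 mid-recovery
        downstroke = (0.5 * (1.0 + np.sin(th))) ** 2
        w = self.recovery_weight + (1.0 - self.recovery_weight) * downstroke
        return -self.radial_peak * np.cos(th) * w

    def burst(self, theta):
        th = np.mod(np.asarray(theta, dtype=float) - self.center + math.pi, TWO_PI) - math.pi
        out = np.zeros_like(th)
        inside = np.abs(th) < self.width / 2.0
        # true raised cosine: 1 at the center, 0 (with zero slope) at the edges
        out[inside] = 0.5 * (1.0 + np.cos(TWO_PI * th[inside] / self.width))
        return out

    @property
    def burst_mean(self) -> float:
        # mean over a revolution of the raised cosine of width W: W / (4 pi)
        return self.width / (4.0 * math.pi)


def jittered_shape(rng: np.random.Generator, body_weight: float = 75.0 * 9.80665) -> PedalShape:
    """Per-trial shape variation (seeded) emulating inter-subject technique."""
    return PedalShape(
        center=rng.normal(math.pi / 2, math.radians(4.0)),
        width=rng.normal(math.radians(170.0), math.radians(6.0)),
        recovery=rng.uniform(0.04, 0.08),
        radial_peak=body_weight * rng.normal(0.22, 0.03),
    )


def tangential_amplitude(power: float, cadence: float, geom: CrankGeometry,
                         shape: PedalShape) -> float:
    """Burst amplitude (N) such that both legs together deliver ``power``."""
    if power < 0:
        raise ValueError("power must be >= 0")
    omega = cadence / 60.0 * TWO_PI
    denom = 2.0 * (shape.burst_mean - shape.recovery) * geom.crank_length * omega
    if denom <= 0:
        raise ValueError("pedal shape delivers no net power")
    return power / denom


def pedal_force_profile(power: float, cadence: float, geom: CrankGeometry,
                        shape: PedalShape | None = None, seed: int | None = None,
                        time=None, crank_angle=None) -> dict[str, PedalLoad]:
    """Smooth periodic pedal loads for both legs at the target power.

    Forces are in the drive convention (force the foot applies to the
    pedal).  The left leg is the right profile shifted by pi.  Returns
    {"r": PedalLoad, "l": PedalLoad} on the supplied time grid (default: two
    revolutions at the pedal-force sampling rate).
    """
    if shape is None:
        shape = jittered_shape(np.random.default_rng(seed)) if seed is not None else PedalShape()
    omega = cadence / 60.0 * TWO_PI
    if time is None:
        period = 60.0 / cadence
        n = int(round(2.0 * period * FORCE_RATE))
        time = np.arange(n + 1) / FORCE_RATE
    time = np.asarray(time, dtype=float)
    theta = omega * time if crank_angle is None else np.asarray(crank_angle, dtype=float)

    amp = tangential_amplitude(power, cadence, geom, shape)
    loads = {}
    for side, offset in (("r", 0.0), ("l", math.pi)):
        th = theta + offset
        f_tan = amp * (shape.burst(th) - shape.recovery)
        f_rad = shape.radial(th)
        tx, ty = pedal_tangent(th)
        rx, ry = np.sin(th), np.cos(th)
        px, py = pedal_position(th, geom)
        loads[side] = PedalLoad(
            time=time.copy(),
            fx=f_tan * tx + f_rad * rx,
            fy=f_tan * ty + f_rad * ry,
            px=px,
            py=py,
        )
    return loads


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTrial:
    meta: TrialMeta
    geom: CrankGeometry
    kin: TrialKinematics
    loads: dict[str, PedalLoad]
    saddle: dict[str, np.ndarray]  # fx, fy, mz on the kinematic grid
    achieved_power: float
    fs_kinematics: float = KINEMATICS_RATE
    fs_forces: float = FORCE_RATE


def _leg_angles(theta, geom: CrankGeometry, thigh, shank, foot_lever):
    qa = geom.ankle_profile(theta)
    px, py = pedal_position(theta, geom)
    hip, knee = leg_inverse_kinematics((px, py), qa, geom, thigh, shank, foot_lever,
                                       crank_angle=theta)
    return hip, knee, qa


def synthesize_trial(meta: TrialMeta, geom: CrankGeometry | None = None,
                     model: MusculoskeletalModel | None = None,
                     shape: PedalShape | None = None,
                     enable_noise: bool = False,
                     noise_angle_sd: float = math.radians(0.3),
                     noise_force_sd: float = 2.0,
                     margin_rev: float = 0.5) -> SyntheticTrial:
    """Generate one dynamically consistent trial.

    The trial spans [-margin_rev, 1 + margin_rev] revolutions around the
    analyzed TDC-to-TDC window, with t = 0 exactly at TDC.  Measurement
    noise (Gaussian on angles and forces, seeded) is optional and off by
    default: the generator emulates the post-residual-reduction state of the
    pipeline, in which kinematics and kinetics are already consistent.  The
    study filters (6 Hz kinematics / 10 Hz forces, zero-phase) are always
    applied.  The tangential amplitude is corrected once for filter droop,
    so the achieved crank power matches the target to numerical precision.
    """
    geom = geom or recreational_geometry(meta.height_m)
    model = model or default_model(meta.height_m, meta.mass_kg)
    rng = np.random.default_rng(meta.seed)
    if shape is None:
        shape = jittered_shape(rng, body_weight=meta.mass_kg * model.gravity)

    period = 60.0 / meta.cadence_rpm
    omega = TWO_PI / period
    thigh = model.segments["thigh_r"].length
    shank = model.segments["shank_r"].length
    foot_lever = model.segments["foot_r"].length

    # kinematic grid with t = 0 on a sample (TDC)
    n0 = int(math.ceil(margin_rev * period * KINEMATICS_RATE))
    n1 = int(math.ceil((1.0 + margin_rev) * period * KINEMATICS_RATE))
    t_kin = np.arange(-n0, n1 + 1) / KINEMATICS_RATE
    theta = omega * t_kin

    angles: dict[str, np.ndarray] = {}
    for side, offset in (("r", 0.0), ("l", math.pi)):
        hip, knee, qa = _leg_angles(theta + offset, geom, thigh, shank, foot_lever)
        if enable_noise:
            hip = hip + rng.normal(0.0, noise_angle_sd, hip.shape)
            knee = knee + rng.normal(0.0, noise_angle_sd, knee.shape)
            qa = qa + rng.normal(0.0, noise_angle_sd, qa.shape)
        pad = int(round(period * KINEMATICS_RATE))
        angles[f"hip_flexion_{side}"] = dual_pass_butterworth(
            hip, KINEMATICS_RATE, KINEMATICS_CUTOFF, padlen=pad)
        angles[f"knee_flexion_{side}"] = dual_pass_butterworth(
            knee, KINEMATICS_RATE, KINEMATICS_CUTOFF, padlen=pad)
        angles[f"ankle_dorsiflexion_{side}"] = dual_pass_butterworth(
            qa, KINEMATICS_RATE, KINEMATICS_CUTOFF, padlen=pad)
    zero = np.zeros_like(t_kin)
    for dof in ("pelvis_x", "pelvis_y", "pelvis_tilt"):
        angles[dof] = zero.copy()
    kin = TrialKinematics(t_kin, theta, angles)

    # pedal forces on the fast grid, filtered, resampled to the kinematic grid
    t_f = np.arange(round(t_kin[0] * FORCE_RATE), round(t_kin[-1] * FORCE_RATE) + 1) / FORCE_RATE
    pad_f = int(round(period * FORCE_RATE))

    def build_loads(target_power: float) -> dict[str, PedalLoad]:
        raw = pedal_force_profile(target_power, meta.cadence_rpm, geom,
                                  shape=shape, time=t_f, crank_angle=omega * t_f)
        out = {}
        for side, load in raw.items():
            fx, fy = load.fx, load.fy
            if enable_noise:
                fx = fx + rng.normal(0.0, noise_force_sd, fx.shape)
                fy = fy + rng.normal(0.0, noise_force_sd, fy.shape)
            fx = dual_pass_butterworth(fx, FORCE_RATE, FORCE_CUTOFF, padlen=pad_f)
            fy = dual_pass_butterworth(fy, FORCE_RATE, FORCE_CUTOFF, padlen=pad_f)
            px, py = forward_kinematics(
                angles[f"hip_flexion_{side}"], angles[f"knee_flexion_{side}"],
                angles[f"ankle_dorsiflexion_{side}"], geom, thigh, shank, foot_lever)
            out[side] = PedalLoad(
                time=t_kin.copy(),
                fx=np.interp(t_kin, t_f, fx),
                fy=np.interp(t_kin, t_f, fy),
                px=px,
                py=py,
            )
        return out

    loads = build_loads(meta.power_w)
    if meta.power_w > 0:
        # the filter slightly attenuates the tangential harmonics; a single
        # proportional correction is exact because the chain is linear
        achieved = crank_power([loads["r"], loads["l"]], theta, geom, time=t_kin)
        loads = build_loads(meta.power_w * meta.power_w / achieved)

    sfx, sfy, smz = saddle_closure(kin, loads, model, geom)
    achieved = crank_power([loads["r"], loads["l"]], theta, geom, time=t_kin) \
        if meta.power_w > 0 else 0.0
    return SyntheticTrial(
        meta=meta, geom=geom, kin=kin, loads=loads,
        saddle={"fx": sfx, "fy": sfy, "mz": smz},
        achieved_power=float(achieved),
    )


# ---------------------------------------------------------------------------
# Trial I/O (.sto/.mot series + JSON sidecar)
# ---------------------------------------------------------------------------


def write_trial(trial: SyntheticTrial, directory: str) -> None:
    """Lossless on-disk representation of a trial (text only)."""
    os.makedirs(directory, exist_ok=True)
    cols = {"crank_angle": trial.kin.crank_angle}
    cols.update(trial.kin.angles)
    stoio.write_sto(os.path.join(directory, "kinematics.sto"),
                    f"{trial.meta.participant_id}_kinematics", trial.kin.time, cols)
    for side, load in trial.loads.items():
        stoio.write_sto(
            os.path.join(directory, f"pedal_{side}.mot"),
            f"{trial.meta.participant_id}_pedal_{side}", load.time,
            {"fx": load.fx, "fy": load.fy, "px": load.px, "py": load.py})
    stoio.write_sto(os.path.join(directory, "saddle.sto"),
                    f"{trial.meta.participant_id}_saddle", trial.kin.time, trial.saddle)
    meta = asdict(trial.meta)
    meta["achieved_power"] = trial.achieved_power
    meta["geometry"] = {
        "crank_length": trial.geom.crank_length,
        "crank_axis": list(trial.geom.crank_axis),
        "saddle_position": list(trial.geom.saddle_position),
        "ankle_profile": asdict(trial.geom.ankle_profile),
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_trial(directory: str) -> SyntheticTrial:
    with open(os.path.join(directory, "meta.json")) as fh:
        meta_d = json.load(fh)
    gd = meta_d.pop("geometry")
    achieved = meta_d.pop("achieved_power")
    meta = TrialMeta(**meta_d)
    geom = CrankGeometry(
        crank_length=gd["crank_length"],
        crank_axis=tuple(gd["crank_axis"]),
        saddle_position=tuple(gd["saddle_position"]),
        ankle_profile=AnkleProfile(**gd["ankle_profile"]),
    )
    _, t, cols, _ = stoio.read_sto(os.path.join(directory, "kinematics.sto"))
    crank = cols.pop("crank_angle")
    kin = TrialKinematics(t, crank, cols)
    loads = {}
    for side in ("r", "l"):
        _, tf, fc, _ = stoio.read_sto(os.path.join(directory, f"pedal_{side}.mot"))
        loads[side] = PedalLoad(time=tf, fx=fc["fx"], fy=fc["fy"], px=fc["px"], py=fc["py"])
    _, ts, sc, _ = stoio.read_sto(os.path.join(directory, "saddle.sto"))
    return SyntheticTrial(meta=meta, geom=geom, kin=kin, loads=loads, saddle=sc,
                          achieved_power=achieved)
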