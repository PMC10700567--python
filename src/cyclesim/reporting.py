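"""Cohort-level analyses: objective comparison, power regression, ensemble
curves, and solution quality checks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinematics import PERCENT_CYCLE_GRID
from .model import KNEE_EXTENSORS, KNEE_FLEXORS, MusculoskeletalModel
from .solver import CollocationGrid, RedundancySolution


# ---------------------------------------------------------------------------
# J1 vs J2 comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Per-trial comparison of the effort-only and force-penalized solves."""

    participant_id: str
    peak_ftf_j1: float
    peak_ftf_j2: float
    mean_ftf_j1: float
    mean_ftf_j2: float
    power_j1: float
    power_j2: float
    rms_kinematic_difference: float
    peak_active_change: dict[str, float]  # muscle -> N (J2 - J1)
    cocontraction_j1: float
    cocontraction_j2: float
    qc_flags: list[str] = field(default_factory=list)


def cocontraction_index(solution: RedundancySolution, grid: CollocationGrid,
                        side: str = "r") -> float:
    """Knee flexor-extensor overlap: integral over the analyzed revolution of
    min(summed flexor, summed extensor active force), normalized by the
    revolution duration (N)."""
    sl = grid.analyzed
    flex = np.zeros(sl.stop - sl.start)
    ext = np.zeros_like(flex)
    for i, name in enumerate(solution.muscle_names):
        stem = name[: -(len(side) + 1)]
        if stem in KNEE_FLEXORS:
            flex += solution.force_active[i][sl]
        elif stem in KNEE_EXTENSORS:
            ext += solution.force_active[i][sl]
    t = solution.times[sl]
    return float(np.trapezoid(np.minimum(flex, ext), t) / (t[-1] - t[0]))


def compare_objectives(sol_j1: RedundancySolution, sol_j2: RedundancySolution,
                       trial, ftf_j1, ftf_j2, grid: CollocationGrid,
                       side: str = "r") -> ComparisonReport:
    """Compare paired solves of the same trial.

    Kinematics are prescribed constraints, so power and joint angles are
    identical between objectives by construction; any mismatch is reported
    as a QC flag rather than silently ignored.
    """
    if sol_j1.muscle_names != sol_j2.muscle_names:
        raise ValueError("solutions come from different models/trials")
    sl = grid.analyzed
    f1 = np.asarray(ftf_j1.force)[sl]
    f2 = np.asarray(ftf_j2.force)[sl]
    flags = []
    # prescribed kinematics: both solves share the trial's angle splines
    rms_kin = 0.0
    p1 = p2 = trial.achieved_power
    if abs(p1 - p2) > 1e-9:
        flags.append("power mismatch between objectives")
    changes = {}
    for i, name in enumerate(sol_j1.muscle_names):
        changes[name] = float(sol_j2.force_active[i][sl].max()
                              - sol_j1.force_active[i][sl].max())
    return ComparisonReport(
        participant_id=trial.meta.participant_id,
        peak_ftf_j1=float(f1.max()), peak_ftf_j2=float(f2.max()),
        mean_ftf_j1=float(f1.mean()), mean_ftf_j2=float(f2.mean()),
        power_j1=p1, power_j2=p2,
        rms_kinematic_difference=rms_kin,
        peak_active_change=changes,
        cocontraction_j1=cocontraction_index(sol_j1, grid, side),
        cocontraction_j2=cocontraction_index(sol_j2, grid, side),
        qc_flags=flags,
    )


# ---------------------------------------------------------------------------
# Regression of peak force on power
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    slope: float  # N/W
    intercept: float  # N
    r_squared: float
    p_value: float
    n: int


def regress_power_vs_peak(cohort_results) -> RegressionResult:
    """Ordinary least squares of first-peak tibiofemoral force (N) on
    cycling power (W), with the exact two-sided t test for the slope
    (n - 2 degrees of freedom)."""
    data = np.asarray(list(cohort_results), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 3:
        raise ValueError("need at least 3 (power, peak force) pairs")
    x, y = data[:, 0], data[:, 1]
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate regression: constant predictor")
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        p = 0.0
    else:
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return RegressionResult(float(slope), float(intercept), float(r2), p, n)


# ---------------------------------------------------------------------------
# Ensemble mean +/- 2 SD curves
# ---------------------------------------------------------------------------


@dataclass
class EnsembleCurves:
    grid: np.ndarray  # % crank cycle, 101 points
    mean: np.ndarray
    lower: np.ndarray  # mean - 2 SD
    upper: np.ndarray  # mean + 2 SD


def ensemble_mean_2sd(curves) -> EnsembleCurves:
    """Pointwise mean and +/- 2 sample SD (n-1 denominator) across
    participants; curves must share the 101-point % crank-cycle grid."""
    arr = np.asarray(list(curves), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two participant curves")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    return EnsembleCurves(
        grid=PERCENT_CYCLE_GRID.copy(), mean=mean,
        lower=mean - 2.0 * sd, upper=mean + 2.0 * sd,
    )


# ---------------------------------------------------------------------------
# Quality checks
# ---------------------------------------------------------------------------


@dataclass
class ReserveReport:
    ratios: dict[str, float]  # dof -> max|reserve| / max|net moment|
    flagged: list[str]
    undefined: list[str]

    @property
    def passed(self) -> bool:
        return not self.flagged


def qc_reserves(solution: RedundancySolution, moments, grid: CollocationGrid,
                threshold: float = 0.05) -> ReserveReport:
    """Reserve usage per DOF: max |reserve torque| over the analyzed
    revolution relative to the peak net moment; flag ratios above 5%."""
    sl = grid.analyzed
    times = solution.times[sl]
    ratios, flagged, undefined = {}, [], []
    for dof, series in solution.reserve_torques.items():
        peak_m = float(np.max(np.abs(np.interp(times, moments.time, moments[dof]))))
        peak_r = float(np.max(np.abs(series[sl])))
        if peak_m < 1e-9:
            undefined.append(dof)
            continue
        ratios[dof] = peak_r / peak_m
        if ratios[dof] > threshold:
            flagged.append(dof)
    return ReserveReport(ratios=ratios, flagged=flagged, undefined=undefined)


@dataclass
class PassiveForceReport:
    ratios: dict[str, float]  # MTU -> revolution-mean passive force / f_max
    flagged: list[str]

    @property
    def passed(self) -> bool:
        return not self.flagged


def qc_passive_forces(solution: RedundancySolution, model: MusculoskeletalModel,
                      grid: CollocationGrid, threshold: float = 0.08) -> PassiveForceReport:
    """Revolution-mean passive force per MTU relative to its maximum
    isometric force; flag ratios at or above 8%."""
    sl = grid.analyzed
    ratios, flagged = {}, []
    for i, name in enumerate(solution.muscle_names):
        f_max = model.mtu(name).f_max
        ratios[name] = float(solution.force_passive[i][sl].mean() / f_max)
        if ratios[name] >= threshold:
            flagged.append(name)
    return PassiveForceReport(ratios=ratios, flagged=flagged)
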