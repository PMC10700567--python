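"""End-to-end orchestration: synthetic trial -> inverse dynamics ->
redundancy solves -> joint reaction -> QC, for single trials and for the
full printed cohort.  This is the code path the analysis scripts, the test
suite, and the acceptance script all share."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import net_joint_moments
from .jrf import JointReactionTrajectory, PeakReport, find_peaks, tibiofemoral_force
from .model import MusculoskeletalModel, default_model
from .reporting import (
    ComparisonReport,
    RegressionResult,
    compare_objectives,
    qc_passive_forces,
    qc_reserves,
    regress_power_vs_peak,
)
from .solver import (
    CollocationGrid,
    ObjectiveConfig,
    RedundancySolution,
    build_problem,
    solve,
)
from .synth import CohortSpec, SyntheticTrial, TrialMeta, sample_cohort, synthesize_trial


@dataclass
class TrialResult:
    meta: TrialMeta
    trial: SyntheticTrial
    model: MusculoskeletalModel
    grid: CollocationGrid
    moments: object
    solutions: dict[str, RedundancySolution]
    ftf: dict[str, JointReactionTrajectory]
    peaks: dict[str, PeakReport]
    reserve_qc: dict[str, object] = field(default_factory=dict)
    passive_qc: dict[str, object] = field(default_factory=dict)
    comparison: ComparisonReport | None = None


def run_trial(meta: TrialMeta, objectives=("J1", "J2"), n_per_rev: int = 51,
              side: str = "r", model: MusculoskeletalModel | None = None,
              verbose: bool = False) -> TrialResult:
    """Run the full per-trial pipeline for one leg.

    J2 solves are warm-started from the J1 solution when both are requested
    (deterministic; the constraints are identical between objectives).
    """
    model = model or default_model(meta.height_m, meta.mass_kg)
    trial = synthesize_trial(meta, model=model)
    moments, inter = net_joint_moments(trial.kin, trial.loads[side], model,
                                       trial.geom, side=side)
    grid = CollocationGrid.from_cadence(meta.cadence_rpm, n_per_rev=n_per_rev)

    solutions, ftf, peaks = {}, {}, {}
    reserve_qc, passive_qc = {}, {}
    warm = None
    for mode in objectives:
        cfg = ObjectiveConfig(mode=mode)
        problem = build_problem(model, trial, moments, cfg, grid, side=side, inter=inter)
        sol = solve(problem, cfg, x0=warm, verbose=verbose)
        solutions[mode] = sol
        if mode == "J1":
            warm = sol.x_raw
        traj = tibiofemoral_force(sol, trial.kin, inter, model, side=side)
        ftf[mode] = traj
        peaks[mode] = find_peaks(traj, grid=grid)
        reserve_qc[mode] = qc_reserves(sol, moments, grid)
        passive_qc[mode] = qc_passive_forces(sol, model, grid)

    comparison = None
    if "J1" in solutions and "J2" in solutions:
        comparison = compare_objectives(solutions["J1"], solutions["J2"], trial,
                                        ftf["J1"], ftf["J2"], grid, side=side)
    return TrialResult(meta=meta, trial=trial, model=model, grid=grid,
                       moments=moments, solutions=solutions, ftf=ftf, peaks=peaks,
                       reserve_qc=reserve_qc, passive_qc=passive_qc,
                       comparison=comparison)


@dataclass
class CohortResult:
    trials: list[TrialResult]
    mean_first_peak: dict[str, float]
    max_reserve_ratio: float  # across trials and sagittal DOFs, J1 solves
    max_passive_ratio: float  # across trials and MTUs, J1 solves
    regression: RegressionResult | None  # peak F_tf (J2) vs power
    failures: list[tuple[str, str]] = field(default_factory=list)


def run_cohort(seed: int = 1, source: str = "table1_rows",
               objectives=("J1", "J2"), n_per_rev: int = 51,
               n_participants: int = 16, progress: bool = False) -> CohortResult:
    """Generate and solve the synthetic cohort; aggregate the headline
    quantities (cohort-mean first peaks, QC maxima, power regression)."""
    spec = CohortSpec(n_participants=n_participants, source=source, seed=seed)
    metas = sample_cohort(spec)
    results, failures = [], []
    for meta in metas:
        try:
            res = run_trial(meta, objectives=objectives, n_per_rev=n_per_rev)
            results.append(res)
            if progress:
                line = f"{meta.participant_id}: power {meta.power_w:.0f} W"
                for mode in objectives:
                    pk = res.peaks[mode]
                    if pk.first_force is not None:
                        line += f"  {mode} first peak {pk.first_force:.0f} N" \
                                f" @ {np.degrees(pk.first_angle):.0f} deg"
                print(line)
        except Exception as exc:  # noqa: BLE001 - cohort report collects failures
            failures.append((meta.participant_id, str(exc)))
            if progress:
                print(f"{meta.participant_id}: FAILED ({exc})")

    mean_first_peak = {}
    for mode in objectives:
        vals = [r.peaks[mode].first_force for r in results
                if r.peaks[mode].first_force is not None]
        mean_first_peak[mode] = float(np.mean(vals)) if vals else float("nan")

    max_res = 0.0
    max_pas = 0.0
    base = objectives[0]
    for r in results:
        rq = r.reserve_qc[base]
        if rq.ratios:
            max_res = max(max_res, max(rq.ratios.values()))
        pq = r.passive_qc[base]
        if pq.ratios:
            max_pas = max(max_pas, max(pq.ratios.values()))

    regression = None
    reg_mode = "J2" if "J2" in objectives else base
    pairs = [(r.meta.power_w, r.peaks[reg_mode].first_force) for r in results
             if r.peaks[reg_mode].first_force is not None]
    if len(pairs) >= 3:
        regression = regress_power_vs_peak(pairs)

    return CohortResult(trials=results, mean_first_peak=mean_first_peak,
                        max_reserve_ratio=max_res, max_passive_ratio=max_pas,
                        regression=regression, failures=failures)
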