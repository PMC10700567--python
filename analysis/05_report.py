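#!/usr/bin/env python
"""Cohort report: ensemble curves, J1-vs-J2 comparison, the power
regression, and the solution quality checks.

Re-runs the pipeline in memory (solutions are cheap enough to recompute),
then writes results/cohort_summary.csv, results/regression.json, ensemble
curve tables, and figures under results/figures/.
"""

import argparse
import json
import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from cyclesim.kinematics import PERCENT_CYCLE_GRID  # noqa: E402
from cyclesim.pipeline import run_cohort  # noqa: E402
from cyclesim.reporting import ensemble_mean_2sd  # noqa: E402


def resample(series, times, grid):
    pct = (times - times[0]) / (times[-1] - times[0]) * 100.0
    return np.interp(PERCENT_CYCLE_GRID, pct, series)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--nodes", type=int, default=51)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    figdir = args.out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    cohort = run_cohort(seed=args.seed, n_per_rev=args.nodes, progress=True)

    rows = []
    ftf_curves = {"J1": [], "J2": []}
    angle_curves = {d: [] for d in ("hip_flexion_r", "knee_flexion_r",
                                    "ankle_dorsiflexion_r")}
    for tr in cohort.trials:
        c = tr.comparison
        rows.append({
            "participant": tr.meta.participant_id,
            "power_W": tr.meta.power_w,
            "cadence_RPM": tr.meta.cadence_rpm,
            "peak_ftf_J1_N": c.peak_ftf_j1,
            "peak_ftf_J2_N": c.peak_ftf_j2,
            "peak_ftf_J1_BW": c.peak_ftf_j1 / (tr.meta.mass_kg * 9.80665),
            "peak_ftf_J2_BW": c.peak_ftf_j2 / (tr.meta.mass_kg * 9.80665),
            "mean_ftf_J1_N": c.mean_ftf_j1,
            "mean_ftf_J2_N": c.mean_ftf_j2,
            "cocontraction_J1_N": c.cocontraction_j1,
            "cocontraction_J2_N": c.cocontraction_j2,
            "max_reserve_ratio": max(tr.reserve_qc["J1"].ratios.values()),
            "max_passive_ratio": max(tr.passive_qc["J1"].ratios.values()),
        })
        sl = tr.grid.analyzed
        t = tr.solutions["J1"].times[sl]
        for mode in ("J1", "J2"):
            ftf_curves[mode].append(resample(tr.ftf[mode].force[sl], t, tr.grid))
        for dof in angle_curves:
            kin_t = tr.trial.kin.time
            sel = (kin_t >= 0) & (kin_t <= 60.0 / tr.meta.cadence_rpm)
            angle_curves[dof].append(
                resample(np.degrees(tr.trial.kin.angles[dof][sel]), kin_t[sel], tr.grid))

    df = pd.DataFrame(rows)
    df.to_csv(args.out / "cohort_summary.csv", index=False)
    print(df[["participant", "power_W", "peak_ftf_J1_N", "peak_ftf_J2_N"]]
          .to_string(index=False))

    reg = cohort.regression
    with open(args.out / "regression.json", "w") as fh:
        json.dump({"slope_N_per_W": reg.slope, "intercept_N": reg.intercept,
                   "r_squared": reg.r_squared, "p_value": reg.p_value, "n": reg.n}, fh,
                  indent=1)
    print(f"\npeak F_tf(J2) vs power: slope {reg.slope:.2f} N/W, "
          f"R^2 {reg.r_squared:.2f}, p {reg.p_value:.2g}")
    print(f"cohort mean first peak: J1 {cohort.mean_first_peak['J1']:.0f} N, "
          f"J2 {cohort.mean_first_peak['J2']:.0f} N")
    print(f"QC: max reserve ratio {100 * cohort.max_reserve_ratio:.2f}% (bound 5%), "
          f"max mean passive {100 * cohort.max_passive_ratio:.2f}% (bound 8%)")

    # ensemble tibiofemoral curves (mean +/- 2 SD)
    fig, ax = plt.subplots(figsize=(6, 4))
    for mode, color, style in (("J1", "tab:blue", "-"), ("J2", "tab:red", "--")):
        ens = ensemble_mean_2sd(ftf_curves[mode])
        pd.DataFrame({"pct": ens.grid, "mean": ens.mean, "lower": ens.lower,
                      "upper": ens.upper}).to_csv(
            args.out / f"ensemble_ftf_{mode}.csv", index=False)
        ax.fill_between(ens.grid, ens.lower, ens.upper, alpha=0.2, color=color)
        ax.plot(ens.grid, ens.mean, style, color=color, label=mode)
    ax.set_xlabel("% crank cycle (0 = TDC)")
    ax.set_ylabel("compressive tibiofemoral force (N)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "tibiofemoral_ensemble.png", dpi=150)

    # joint angles ensemble
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, (dof, curves) in zip(axes, angle_curves.items()):
        ens = ensemble_mean_2sd(curves)
        ax.fill_between(ens.grid, ens.lower, ens.upper, alpha=0.25)
        ax.plot(ens.grid, ens.mean)
        ax.set_title(dof.replace("_r", ""))
        ax.set_xlabel("% crank cycle")
    axes[0].set_ylabel("angle (deg)")
    fig.tight_layout()
    fig.savefig(figdir / "joint_angles_ensemble.png", dpi=150)

    # regression scatter
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df.power_W, df.peak_ftf_J2_N)
    xs = np.linspace(df.power_W.min(), df.power_W.max(), 10)
    ax.plot(xs, reg.intercept + reg.slope * xs, "k--",
            label=f"y = {reg.slope:.1f}x + {reg.intercept:.0f}, R$^2$={reg.r_squared:.2f}")
    ax.set_xlabel("cycling power (W)")
    ax.set_ylabel("peak tibiofemoral force, J2 (N)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "power_regression.png", dpi=150)
    print(f"tables and figures written under {args.out}")


if __name__ == "__main__":
    main()
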