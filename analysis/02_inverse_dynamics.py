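#!/usr/bin/env python
"""Net joint moments of every generated trial.

Runs the Newton-Euler recursion on each trial in results/trials/, writes
the right-leg net moments as .sto under results/moments/, and prints the
per-DOF ranges over the analyzed revolution.
"""

import argparse
import pathlib

import numpy as np

from cyclesim import io as stoio
from cyclesim.dynamics import net_joint_moments, pedal_force_check
from cyclesim.model import default_model
from cyclesim.synth import read_trial


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", type=pathlib.Path, default=pathlib.Path("results/trials"))
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results/moments"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for tdir in sorted(args.trials.iterdir()):
        if not (tdir / "meta.json").exists():
            continue
        trial = read_trial(tdir)
        model = default_model(trial.meta.height_m, trial.meta.mass_kg)
        mom, inter = net_joint_moments(trial.kin, trial.loads["r"], model,
                                       trial.geom, side="r")
        fx, fy = pedal_force_check(trial.kin, model, trial.geom, inter, side="r")
        check = max(np.max(np.abs(fx - trial.loads["r"].fx)),
                    np.max(np.abs(fy - trial.loads["r"].fy)))
        stoio.write_sto(args.out / f"{trial.meta.participant_id}_moments.sto",
                        f"{trial.meta.participant_id}_net_moments",
                        mom.time, dict(mom.moments))
        spans = {d.split("_")[0]: (m.min(), m.max()) for d, m in mom.moments.items()}
        print(f"{trial.meta.participant_id}: "
              + "  ".join(f"{k} [{lo:6.1f},{hi:6.1f}] N*m" for k, (lo, hi) in spans.items())
              + f"  (free-body check {check:.1e} N)")
    print(f"moments written to {args.out}")


if __name__ == "__main__":
    main()
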