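# cyclesim

Muscle-driven simulation of seated cycling on a planar musculoskeletal
model: prescribed-kinematics muscle-redundancy solving by direct
collocation, tibiofemoral joint-reaction analysis, and cohort-level
reporting — runnable end to end on synthetic, dynamically consistent
trials, with no external data.

## The scientific problem

Net joint moments from inverse dynamics do not determine individual muscle
forces: the lower limb has more muscles than sagittal degrees of freedom.
`cyclesim` resolves this redundancy for pedaling by transcribing an optimal
control problem — muscle excitations `e_i(t)`, activations `a_i(t)`,
compliant-tendon states `z_k(t)` and reserve/residual controls `u_j(t)` on
a collocation grid, constrained by per-node moment balance, Hill-type
muscle-tendon force balance and first-order activation dynamics — and
minimizing either an effort functional

    J1 = w1 ( Σ_i ∫ e_i²(t) dt + Σ_j ∫ u_j²(t) dt ) + w2 Σ_k ∫ ż_k²(t) dt

with w1 = 2, w2 = 1e-6, or the same effort plus a penalty on the squared
compressive tibiofemoral force of both legs,

    J2 = J1 + w3 Σ_legs ∫ F_tf²(t) dt ,      w3 = 1e-3 ,

with solver tolerances of 1e-3.  `F_tf` is assembled as the free-body sum
over the tibia: the axial intersegmental knee force plus every
knee-crossing muscle's force projected on the tibial axis.  Comparing the
two objectives quantifies how much knee loading is attributable to muscle
coordination rather than to the task: the penalty redistributes
plantarflexion from the gastrocnemii to the soleus and removes
flexor–extensor co-contraction while leaving the pedaling power and the
kinematics untouched.

The package is laid out as an analysis project: every computation lives in
the library under `src/cyclesim/` (model, crank kinematics and filtering,
Newton–Euler inverse dynamics, synthetic-trial generation, the collocation
solver, joint-reaction assembly, reporting), and the numbered scripts under
`analysis/` narrate the analysis pipeline over it.

## Worked example

Solve one mid-power trial (137 W at 85 RPM, the cohort-mean condition)
under both objectives and report the knee loading:

```python
import numpy as np
from cyclesim.pipeline import run_trial
from cyclesim.synth import TrialMeta

meta = TrialMeta("demo", height_m=1.75, mass_kg=75.0,
                 cadence_rpm=85.0, power_w=137.0, seed=42)
res = run_trial(meta, objectives=("J1", "J2"))

for mode in ("J1", "J2"):
    pk = res.peaks[mode]
    print(f"{mode}: first peak {pk.first_force:6.0f} N "
          f"at {np.degrees(pk.first_angle):4.0f} deg, "
          f"status {res.solutions[mode].status}")
print(f"max reserve ratio {100 * max(res.reserve_qc['J1'].ratios.values()):.2f} %")
print(f"max mean passive  {100 * max(res.passive_qc['J1'].ratios.values()):.2f} %")
```

prints

```
J1: first peak   1627 N at   96 deg, status acceptable
J2: first peak    768 N at  110 deg, status acceptable
max reserve ratio 0.03 %
max mean passive  2.55 %
```

i.e. the effort-only solution loads the knee with about two body weights in
the downstroke; penalizing the tibiofemoral force halves that peak at
identical power and kinematics, with reserve torques far below 5 % of the
peak net moments and revolution-mean passive forces far below 8 % of
maximum isometric force.

The cohort pipeline is the same code at scale:

```sh
python analysis/01_generate_cohort.py      # 16 synthetic trials (printed cohort rows)
python analysis/02_inverse_dynamics.py     # net joint moments per trial
python analysis/03_solve_redundancy.py     # 32 collocation solves (J1 + J2)
python analysis/04_joint_reaction.py       # tibiofemoral peaks table
python analysis/05_report.py               # ensembles, regression, QC, figures
```

All intermediate artifacts are plain-text `.sto/.mot/.csv/.json` under
`results/`.

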