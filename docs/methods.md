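# Methods

`cyclesim` reproduces a muscle-driven simulation pipeline for seated
cycling: prescribed-kinematics muscle-redundancy solving by direct
collocation under two objective functionals, followed by a tibiofemoral
joint-reaction analysis and cohort-level reporting.  Everything runs on
synthetic, dynamically consistent trials, so the full pipeline is testable
without any data downloads.  This note documents the model, the numerical
choices, and what the synthetic cohort does and does not represent.

## The musculoskeletal model

The model is a planar (sagittal) reduction of the lower limb: a stationary
pelvis segment (lumping the torso), and thigh-shank-foot chains per leg,
with hip flexion, knee flexion, and ankle dorsiflexion as the actuated
degrees of freedom (flexion/flexion/dorsiflexion positive).  Segment
lengths, masses, mass-center offsets and radii of gyration follow standard
anthropometric fractions of stature and body mass (thigh 0.245 H / 0.100 M,
shank 0.246 H / 0.0465 M, foot lever 0.0835 H / 0.0145 M).  Scaling to a
participant is parametric: lengths (including optimal fiber and tendon
slack lengths, moment arms and insertion offsets) scale with the height
ratio, masses with the mass ratio, inertias with mass x height^2; maximum
isometric forces are unchanged; pelvis residual capacities are re-sized to
the new body weight (vertical residual: 1 body weight; the other pelvis
DOFs: 0.5 BW -- the per-DOF allocation is our choice, the total follows the
1-BW rule).

Sixteen muscle-tendon units per leg (the familiar sagittal set: three
glutei-group units are merged into gluteus maximus + medius, iliacus,
psoas, rectus femoris, three vasti, the four hamstring units, both
gastrocnemii, soleus, tibialis anterior).  Per-muscle maximum isometric
forces, optimal fiber lengths, tendon slack lengths and pennation angles
are independent literature-scale choices for an adult lower limb; they are
deliberately *not* copied from any specific published model file.  Muscle
paths are represented by per-DOF moment-arm polynomials (radians in, meters
out) fit to published anatomical curves: the quadriceps knee moment arm
follows the measured patellar-tendon shape (peak ~4.5 cm near 30 deg of
flexion, declining to ~3.0 cm at 90 deg and ~2.0 cm in deep flexion);
hamstring knee moment arms peak mid-flexion; both biceps femoris heads
remain knee flexors over 0-150 deg of flexion by construction.  MTU length
is *defined* by tendon excursion from a mid-cycling reference posture (hip
0.9, knee 1.3, ankle 0 rad), which makes moment arms and lengths consistent
to machine precision.

Hill curves are continuous and differentiable everywhere (a requirement of
gradient-based collocation): a three-Gaussian active force-length curve and
a log-arcsinh force-velocity curve, both renormalized so fl(1) = 1 and
fv(0) = 1 exactly; a single-exponential passive curve (1% of maximum force
at optimal length, reaching 100% at 60% strain -- positive and strictly
increasing everywhere, so passive force never changes sign); and an
exponential tendon reaching maximum isometric force at 4.9% strain
(stiffness parameter 35).  A small parallel fiber damper (0.1 dimensionless
force per normalized velocity, Millard-style) is part of the passive
element; it regularizes the tendon force balance when activation vanishes
and averages out of revolution-mean passive forces.

The rigid-tendon rule is structural: a tendon is rigid exactly when its
slack length is strictly shorter than the optimal fiber length (a tie is
compliant).  With our parameters this leaves 4 rigid and 12 compliant units
per leg.  Activation dynamics are first order with smoothly blended time
constants (10 ms activation / 40 ms deactivation, logistic blend of
steepness 20 in e - a, differentiable at e = a).

## Synthetic trials

The generator emulates the conditions of a 16-participant
recreational cohort (power 40-216 W, cadence 75-92 RPM, stature
159.8-195.4 cm, mass 54.2-92.3 kg), reproduced verbatim as the default
cohort; uniform sampling within those ranges is also available.

Bike fit is anthropometric: crank length scales with stature (172.5 mm at
1.75 m, clipped to 160-177.5 mm), and the hip center sits along a 74 deg
seat tube at 0.97 x 0.883 x (0.48 H) from the crank axis -- the saddle-
height formula with an inseam proxy and a hip-above-saddle correction, set
to the highest value for which every cohort stature can reach the whole
pedal circle.  The ankle follows a smooth two-harmonic dorsiflexion profile
(most dorsiflexed near TDC, most plantarflexed near BDC); given that
profile the leg inverse kinematics is an exact two-link solution wrapped in
a fixed-point iteration on the shank angle (the foot lever moves the
target), converging to 1e-14 and round-tripping through forward kinematics
below 1e-9 m.

Pedal loads are stored in the drive convention (force the foot applies to
the pedal).  The tangential component is a raised-cosine downstroke burst
(center 90 deg, width ~170 deg) minus a small constant recovery drag, with
the amplitude set in closed form so that both legs together deliver the
target power; after the 10 Hz filter a single proportional correction makes
the achieved crank power exact (the chain is linear).  The mechanically
ineffective radial component is power-independent and weight-proportional
(~0.22 BW): pressing down compresses the crank near TDC and extends it near
BDC (-cos theta), attenuated through the recovery half where the leg
partially unweights.  Per-trial seeded jitter of the burst center, width,
drag and radial magnitude emulates inter-subject technique and produces
non-degenerate ensemble bands.

The reference measurement chain is applied always: kinematics sampled at
112.5 Hz and low-passed with the zero-phase second-order 6 Hz Butterworth
filter (reflective padding of one revolution); pedal forces at 450 Hz,
low-passed at 10 Hz and resampled to the kinematic grid.  Optional seeded
Gaussian measurement noise (0.3 deg on angles, 2 N on forces, pre-filter)
is off by default: the generator emulates the *residual-reduced* stage of
the original pipeline, in which kinematics and kinetics are already
consistent.  Velocities and accelerations are analytic derivatives of cubic
splines of the (filtered) angles, never finite differences, so inverse
dynamics sees internally consistent kinematics.

Dynamic consistency is closed explicitly: the saddle reaction stored with
each trial is the exact closure of the pelvis Newton-Euler balance given
both legs' hip loads, so the residual demand beyond the saddle is zero to
numerical precision, and the solver's pelvis residual actuators (the
saddle-interaction stand-ins) remain essentially unused -- mirroring the
role residual actuators play after residual reduction in the original
pipeline.

What the generator does *not* emulate: marker trajectories and soft-tissue
artifact, pedal-cleat interface mechanics, intra-subject revolution-to-
revolution variability, frontal-plane motion, and the asymmetries of real
riders.  Passing tests therefore demonstrate the correctness and behavior
of the method on idealized planar trials, not validity against any real
recording.

## The redundancy solver

The optimal control problem is transcribed by trapezoidal defect
collocation on 51 nodes per revolution (default) plus a quarter-revolution
lead-in before TDC that is solved but excluded from analysis; TDC and
TDC + one revolution are grid nodes by construction.  Decision variables at
every node: muscle excitations e and activations a (0-1), actuator controls
u (-1..1, scaled by capacity), and for each compliant tendon the auxiliary
state z (normalized fiber length) with its derivative zdot as an implicit
control.  Constraints: per-DOF moment balance at every node (muscle forces
via moment arms, plus reserve/residual actuators, equal the net moment);
the tendon force balance of every compliant unit (an algebraic path
constraint whose residual the implicit dynamics drive to zero); trapezoidal
defects of the activation and auxiliary dynamics; and the initial
excitation-activation tie.  Trapezoidal transcription was chosen over
Hermite-Simpson because at 51 nodes/revolution it already resolves the
~1.4 Hz crank dynamics while halving the problem size; the scheme remains a
labelled field of the grid.

The objectives are the two reference functionals: J1 = w1 (sum int e^2 + sum int
u^2) + w2 sum int zdot^2 with w1 = 2 and w2 = 1e-6, and J2 = J1 + w3 sum
over legs of int F_tf^2 with w3 = 1e-3 (1/N^2/s, from dimensional
bookkeeping).  F_tf inside J2 is assembled from the same decision variables
as the constraints, so the penalty is smooth and exact.  Because the
synthetic cohort is bilaterally symmetric, the left leg's integral equals
the right's and is handled by a factor of two; each solve covers one leg.
Reserve torque actuators have 0.5 N*m capacity (expensive relative to
muscles, per-control quadratic cost, and sized so that even a railed
reserve stays within the 5%-of-peak-net-moment quality bound at the
lowest cohort power); pelvis residuals are sized by the
1-BW rule and sit against a zero post-saddle demand.

No off-the-shelf nonlinear-programming library is assumed; the solver is a
purpose-built sparse penalty-barrier Newton method (`cyclesim.ipsolver`):
bounds through a log barrier with safeguarded dual estimates, equalities
through a quadratic penalty (rho from 1e4, increased tenfold when needed),
full Newton steps on the penalty-barrier function with a projected-arc
Armijo search, exact first derivatives and an exact-where-it-matters
Hessian (the convex objective exactly; constraint curvature -- the stiff
tendon exponential and the activation blend -- via the penalty's implicit
multipliers once near-feasible).  Diagonal variable scaling (every box to
width one) and gradient-based objective scaling (max gradient ~100 at the
start) follow standard practice.  Convergence demands constraint residuals
and the KKT stationarity (measured against least-squares multipliers, with
the customary dual-size scaling) at 1e-3 on the scaled problem -- the
study's tolerance; an `acceptable` status (feasible to 1e-3, objective flat
over eight iterations, scaled dual infeasibility below 5) handles the
limit-cycling that penalty methods exhibit at their rounding floor, and the
status is recorded on every solution.  The initial guess is deterministic:
a per-node static-optimization QP (rigid-equivalent muscle coefficients),
with compliant fiber lengths from the isometric tendon balance by
vectorized bisection; J2 warm-starts from the J1 solution of the same
trial, which is legitimate because the two problems share their entire
constraint set.

Two regularizations deserve explicit mention.  First, the parallel fiber
damper (above) removes the rank deficiency of the tendon balance at zero
activation.  Second, a small integral of squared excitation *rate*
(weight 2e-3) is added inside the solver only: the asymmetric
activation/deactivation rates make sawtooth excitation chatter spuriously
cheap under the raw effort integral (a genuine relaxed-control phenomenon
of the continuous problem, not a discretization bug), and the rate penalty
removes it without measurably changing activations or forces.  Reported
objective values never include this term.

## Joint reaction and reporting

The compressive tibiofemoral force is the free-body sum over the isolated
tibia: the axial component of the muscle-free intersegmental knee force
plus every knee-crossing unit's total (active + passive) force projected
onto the tibial long axis.  Each knee-crossing unit carries an effective
insertion distance d; with moment arm r its line of action makes
sin(phi) = |r|/d with the tibial axis, so the compressive cosine is
sqrt(1 - (r/d)^2), nonnegative by construction (the monotonicity of the
assembly in any muscle force follows).  The d values encode anatomical
line-of-action obliquities (patellar tendon ~20-25 deg mid-flexion,
hamstrings ~15-25 deg, gastrocnemii ~20 deg).  Anterior-posterior shear and
the medial/lateral split are out of scope.

Peaks are located on the analyzed TDC-to-TDC revolution: local maxima with
quadratic refinement (1% prominence floor; flat plateaus are not peaks);
the first peak is the largest in (0, 180) deg of crank angle, the second
the largest remaining one in (90, 180) deg; an absent second peak is
reported as absent, never invented.

Cohort reporting: ensemble mean +/- 2 sample SD on a 101-point % crank
cycle grid; ordinary least squares of first-peak force on power with the
exact t test (n - 2 df); a co-contraction index defined (since the source
concept is qualitative) as the revolution-mean of min(summed knee-flexor,
summed knee-extensor active force); reserve QC (max |reserve| / max |net
moment| <= 5% per DOF) and passive QC (revolution-mean passive force < 8%
of maximum isometric force per MTU).

## Problem sizes and determinism

The standard cohort analysis solves 16 trials x 2 objectives on the default
51-node grid; a full-size problem has ~4000 variables and ~2900 equality
constraints and solves in seconds on one core.  Unit tests use 21-node
grids.  All randomness (cohort sampling, per-trial technique jitter,
optional noise) flows from a single integer seed through per-trial derived
seeds; solves are deterministic given the guess, so repeated runs are
bit-identical.

## Known limitations

* Planar model: no frontal-plane loads, no hip ad/abduction or rotation;
  the knee range of motion of the synthetic fit (about 50-120 deg) is
  somewhat more flexed than typical riding because the planar chain must
  reach the whole pedal circle for the shortest participant.
* The effort-optimal solutions of a 16-muscle planar model co-contract
  less than an 80-muscle 3D model: the force-penalized objective can
  eliminate gastrocnemius-hamstring co-contraction almost entirely, so the
  penalized tibiofemoral level sits below the original study's (~800 N
  cohort-mean first peak versus ~1200 N), while the effort-only level and
  the direction and ordering of every muscle-level change are reproduced.
* The tibiofemoral assembly ignores patellofemoral mechanics and wraps the
  extensor mechanism into an effective insertion; magnitudes, not contact
  mechanics, are in scope.
* Imported (non-synthetic) trials are supported by the same I/O and
  inverse-dynamics paths, but residual reduction is not implemented:
  residual demands are reported, not reduced.
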