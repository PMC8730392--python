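# Methods

`exogait` simulates muscle-driven sagittal-plane walking by direct
collocation: given one gait cycle of prescribed kinematics, muscle-tendon
geometry and net joint moments, it solves the muscle redundancy problem —
distribute the hip, knee and ankle moments among nine Hill-type
muscle-tendon units so that a smoothed metabolic cost is minimized — with
and without ideal assistive torques. This note documents the models, the
numerical choices, and what the synthetic data do and do not establish.

## Musculoskeletal model

Nine lumped sagittal-plane muscles per leg (gluteus maximus, biarticular
hamstrings, iliopsoas, rectus femoris, vasti, biceps femoris short head,
gastrocnemius, soleus, tibialis anterior), each a Hill-type
muscle-tendon unit: contractile fiber with active force-length,
force-velocity and parallel passive elasticity, in series with a nonlinear
elastic tendon, under a constant-height pennation model
(`l_m sin(alpha) = l_m_opt sin(alpha_opt)`). The default parameter table
(`src/exogait/data/muscles.yaml`) holds nominal merged-muscle values for a
~75 kg adult; merging sums maximum isometric forces and averages lengths.

All characteristic curves are smooth (at least C1) because the NLP solver
consumes exact derivatives:

* active force-length: `exp(-(l̃-1)^2 / 0.45)` (exactly 1 at optimal length);
* passive force-length: `(exp(4 (l̃-1)/e0M) - 1) / (exp(4) - 1)` — exactly 0
  at optimal length and 1 at `1 + e0M` (default passive strain `e0M = 0.6`);
  mildly negative below optimal length, which keeps it smooth;
* force-velocity: `1 + d1 asinh(8 ṽ)` with `d1 = 1/asinh(8)`, exactly 1 at
  zero velocity and 0 at maximal shortening (`ṽ = -1`); the eccentric branch
  is the smooth continuation of the same curve;
* tendon force-length: `c1 (exp(35 (l̃t - 1)) - 1)` with `c1` chosen so the
  force is exactly 1 at `1 + e0T` (default tendon strain `e0T = 0.049`);
  closed-form inverse. The curve is extended smoothly below slack length
  (small negative normalized force, bounded at -0.02 in the NLP), a standard
  device that keeps near-slack dynamics well-defined.

Activation dynamics are first-order with a tanh blend between activation and
deactivation time constants (defaults 15/60 ms), the deactivation rate
scaled by `0.5 + 1.5 a`. Fiber damping 0.01 (dimensionless, on normalized
velocity) regularizes the force-velocity inversion.

Tendon compliance is handled *implicitly*: the normalized tendon force is a
state, its time derivative a control, and the Hill equilibrium residual an
algebraic path constraint. Fiber kinematics follow from the inverted tendon
curve, so no stiff explicit ODE appears.

## Metabolic energetics

Instantaneous muscle metabolic rate = activation/maintenance heat +
shortening/lengthening heat + contractile-element work rate, scaled by
muscle mass (`f_max / sigma * l_m_opt * rho`, specific tension 0.25 MPa,
density 1059.7 kg/m3). Coefficients: maintenance heat `128 ft + 25` W/kg
muscle (`ft` = fast-twitch fraction), shortening coefficients
`100/(v_max/2.5)` (slow) and `153/v_max` (fast), lengthening coefficient 4x
the slow shortening coefficient with first-power activity scaling, aerobic
scale 1.5, activity measure `A = e` when `e > a` else `(e+a)/2`, `A^0.6`
scaling of maintenance heat and `A^2` of shortening heat, and the
`0.4 + 0.6 f_iso` / `f_iso` length corrections above optimal fiber length.

Every conditional is replaced by a C1 surrogate: tanh switches with a single
sharpness parameter (default 40; the excitation-vs-activation switch is 4x
sharper because its argument varies on a smaller scale) and a smooth ramp
`0.5(x + sqrt(x^2 + eps^2))` for the velocity split and the non-negativity
clamp. The clamp width is proportional to the activity measure so an
inactive muscle dissipates exactly zero. An independently coded, hard-
conditional reference implementation (`metabolics_reference`) is the oracle:
the smoothed rate agrees within 2% over a physiological state grid and
converges monotonically to the reference as the sharpness grows.

Whole-body reporting: gross average total rate =
`2 * ∫ Σ muscle rates dt / (duration * body mass) + 1.2 W/kg` basal; the
factor 2 reflects left-right symmetry when one leg is simulated. Per-muscle
averages use the same convention without the basal term. Percent changes
(total and per muscle) are expressed relative to the *unassisted gross
total*, so per-muscle changes sum exactly to the total change. Reporting
integrals use trapezoidal quadrature on the solution grid, independent of
the transcription.

## Devices

Ideal massless torque actuators in five semantic directions with
mass-normalized peak torques of 1.0 N·m/kg per hip or knee direction and
2.0 N·m/kg for ankle plantarflexion. Torques are unidirectional
(assistive direction only). Multi-joint devices are driven either by one
control trajectory per direction in [0, 1] ("independent") or by a single
shared trajectory scaled by static per-direction gains in [0, 1]
("coupled"). Coupled feasible torque sets are subsets of independent ones,
which yields the structural objective orderings the acceptance tests check.
The 16 conditions are 1 unassisted + 5 single-joint + 5 coupled + 5
independent multi-joint.

## Transcription and solver

States: activations and normalized tendon forces (9 + 9). Controls:
excitations, tendon-force derivatives, 3 reserve torques, device controls.
Constraints: dynamics defects (trapezoidal rule by default; a one-point
Radau scheme — right-endpoint implicit Euler — is the config alternative),
the Hill equilibrium residual at every node, per-DOF moment balance
`Σ r F + τ_device + τ_reserve = τ_net` scaled by body mass, and periodicity
of the muscle states. Default mesh 100 intervals/s (50/s for the desk-scale
studies here); mesh refinement bisects intervals whose dynamics error —
estimated by an independent RK4 integration across each interval — exceeds
1e-3.

Objective: metabolic term (W/kg, including the basal offset for
interpretability) plus secondary terms that aid convergence: squared
excitation and activation (weight 0.05 each), squared scaled tendon-force
derivative (0.01), squared device control (1e-3, for uniqueness of saturated
devices), and heavily penalized squared reserves (2e3 on torques scaled by
1 N·m/kg of body mass). The metabolic term dominates by two to three orders
of magnitude in all solutions.

The NLP is solved with SciPy's interior-point trust-region method.
Derivatives come from a colored complex-step engine: constraint rows are
node-local, so columns with disjoint row supports share a complex-step
evaluation; ~10 colors suffice for the constraint Jacobian regardless of
mesh size, and gradients are exact to machine precision. Constraint
curvature is omitted (Gauss-Newton style); the objective Hessian is a
compact limited-memory BFGS approximation (30 pairs, O(mn) products) for the
moment-matching problems and a dense BFGS for the parameter-tracking
problems, whose static variables are more ill-conditioned. Variables are
scaled to O(1) (tendon-force rates by 20/s, reserves by body mass). The
convergence tolerance maps to the solver's stationarity tolerance with a
factor 1/3, chosen so that a nominal 1e-3 solve sits within 1% (in
objective) of a 1e-4 solve — the sensitivity study verifies this.

Warm-start cascade (deterministic): the unassisted problem starts from a
per-node nonnegative-least-squares distribution of the net moments and is
solved coarse (20/s) before fine; single-joint devices start from the
unassisted solution; independent multi-joint devices from their best
constituent single; coupled devices from their independent counterpart
collapsed onto one shared control; and if a coupled solve finds a better
basin than its independent counterpart, the independent problem is re-solved
from it (every coupled control is reachable independently, so the ordering
is restored by descent). Warm starts begin with a nearly converged barrier
parameter; interior-point path-following from the default barrier weight
otherwise walks away from the supplied basin.

## Calibration

1. **Force scaling.** Every maximum isometric force is scaled by the ratio
   of predicted lower-limb muscle volume at the subject's mass to the
   volume at the 75 kg reference, using a documented linear volume-mass
   regression (`v = 47 m + 1285` in cm3, config-overridable).
2. **Passive fit.** `{l_m_opt, l_t_slack, passive strain}` are fitted to
   passive joint moments at static multi-joint postures under a rigid-tendon
   assumption: weighted least squares on moments plus a small normalized
   passive-force penalty (1e-4) and a deviation penalty (1e-3) that keeps
   weakly identified muscles near their initial values; ±25% bounds. The
   three parameter families trade off against each other on smooth posture
   sets, so single-family fits (`free_params=`) are offered for well-posed
   recovery studies.
3. **EMG refit.** `l_m_opt` and `l_t_slack` (passive strains frozen) become
   static decision variables of the tracking OCP, bounded to ±25% of their
   step-2 values. The primary objective is the squared EMG-excitation error
   over measured muscles (unmeasured muscles, e.g. iliopsoas, are simply
   excluded); secondary terms are small activation/excitation efforts, a
   passive-force penalty (1e-3) and a parameter-deviation anchor (0.2) —
   without the anchor, muscles that are nearly silent in the cycle are
   unidentifiable and drift to their bounds. The solve is two-stage
   (trajectories first with parameters frozen, then jointly), with the
   stationarity tolerance tightened to 1e-5 because tracking objectives are
   O(1e-2). When the cycle is sampled on a uniform grid at least as fine as
   the requested mesh, the collocation nodes are placed on the samples so no
   interpolation bias enters the parameter estimates.

## Synthetic data

The generator emulates one ~1.1 s cycle of treadmill walking at 1.25 m/s for
a typical 72.4 kg healthy adult. Joint angles and template
moments are low-order periodic harmonics with physiological magnitudes
(moments of order 1 N·m/kg). Geometry is analytic: moment arms are
polynomials in the spanned joint angle with anatomical signs (e.g. soleus
plantarflexion arm ≈ 0.046 m), MTU lengths are the corresponding
antiderivatives, so `r = -∂l/∂θ` holds exactly and MTU velocities follow by
the chain rule. EMG noise, when requested, is multiplicative log-normal with
a small additive floor.

The *ground-truth* dataset drives the muscles with smooth periodic
excitation bumps and integrates activation and tendon dynamics forward with
the same implicit trapezoidal rule used by the transcription, on the output
grid itself, over two cycles for periodicity. The cycle's net moments are
then defined as the muscle-generated moments, so the true trajectories are
feasible with zero reserves and exactly representable on a coinciding mesh —
recovery tests therefore measure identifiability, not discretization bias.
The excitation programs were chosen (once, as part of the generator design)
so that the true coordination is near the metabolic optimum of the
transcribed problem; this is what makes "solve the unassisted problem and
recover the truth" a meaningful oracle. Two muscles (gastrocnemius, biceps
femoris short head) end up nearly silent in this synthetic gait, which is
why the calibration stage needs its deviation anchor.

What the synthetic data do *not* contain: measurement noise in kinematics
and moments, soft-tissue artifact, electromechanical delay between EMG and
excitation, frontal-plane and upper-body musculature, kinematic adaptation
to assistance, or any inter-subject variability beyond seeded noise. Passing
recovery tests on these data shows the pipeline is internally consistent and
well-identified under its own model class; it does not validate the model
against real walking.

## Problem sizes and determinism

Desk-scale studies use a mesh of 50 intervals/s (55 intervals per 1.1 s
cycle, ~2 300 NLP variables), a 20/s coarse presolve, and the 16-condition
suite; the calibration study uses a 56-sample cycle whose grid doubles as
the mesh. Every stochastic input is driven by an explicit seed; solves are
deterministic given identical inputs and configuration.

## Known limitations

* The interior-point solver can settle in distinct local basins; the
  warm-start cascade and cross-polish make the reported orderings reliable,
  but isolated cold-started solves may land a few percent above the best
  known objective.
* The trapezoidal (2nd-order) transcription needs ~50+ intervals/s before
  activation-dynamics discretization error is negligible; the one-point
  Radau alternative is only first-order and is intended for scheme
  cross-checks, not production runs.
* Coupled-vs-independent gaps on the synthetic cycle are larger than would
  be expected for real gait, because the synthetic moment patterns make one
  direction dominate each combination; trends (orderings), not magnitudes,
  are the meaningful desk-scale quantities.
* The energetics model inherits the known tendency of muscle-level models to
  underestimate whole-body walking cost; no correction is applied.
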