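# Methods

`myofatigue` simulates force production and localized fatigue of the elbow
flexor/extensor group during high-intensity static and cyclic tasks.  It
couples three model layers — rigid-tendon Hill-type musculotendon
mechanics, load-sharing optimization over the redundant muscle set, and a
three-compartment motor-unit fatigue model — plus the subject-specific
calibration procedures each layer needs.  This note records the model
equations as implemented, the defaults and the reasoning behind every
genuinely open design choice.

## Musculotendon mechanics

Each muscle is a rigid-tendon Hill actuator.  Force along the tendon is

    F_MT = (F_CE + F_PE) cos(alpha)
    F_CE = F0M * a * f_l(l_n) * f_v(v_n)
    F_PE = F0M * f_PE(l_n)

with `a` the activation, `l_n = lM/l0M` and `v_n` the fiber velocity
normalized by the maximal shortening velocity.  Excitation equals
activation throughout — there are no activation dynamics anywhere in the
package, consistent with the quasi-static treatment of slow voluntary
efforts.  With the tendon frozen at its slack length `lST`, fiber
kinematics follow directly from the joint state:
`lM cos(alpha) = lMT - lST`, constant-thickness pennation
`lM sin(alpha) = l0M sin(alpha0)`, and `vM = vMT cos(alpha)`.

The physiological force bounds handed to the optimizer are the a=0 and a=1
forces:

    F_min = f_PE * F0M * cos(alpha)
    F_max = (f_l f_v + f_PE) * F0M * cos(alpha)

and the inverse map recovers the activation of an optimized force,
`a = (F_MT/cos(alpha) - F_PE) / F_CE_max`.

**Curve shapes.**  The three dimensionless curves are only constrained
qualitatively by the physiology (bell-shaped active force–length peaking
at the optimum; force–velocity equal to 1 isometrically, zero at maximal
shortening, bounded eccentric plateau; passive force zero at or below the
optimal length).  The implemented forms are standard smooth choices:

| curve | form | defaults |
|---|---|---|
| `f_l` | Gaussian `exp(-((l_n-1)/gamma)^2)` | `gamma = 0.45` |
| `f_v`, shortening | Hill hyperbola `(1+v_n)/(1 - v_n/a_f)`, `v_n in [-1,0]` | `a_f = 0.25` |
| `f_v`, lengthening | `f_ecc - (f_ecc-1) exp(-v_n/b)`, slope-matched at 0 | `f_ecc = 1.4` |
| `f_PE` | `expm1(k (l_n-1)/e0)/expm1(k)` for `l_n > 1`, else 0 | `k = 4`, `e0 = 0.6` |

The maximal shortening velocity is `10 l0M` per second per muscle.  All
shape constants live in `HillCurves` and can be overridden; different
published curve families will shift absolute force traces, which is why no
numerical agreement with any particular external implementation is
claimed.  Velocity sign convention: lengthening positive.

## Three-compartment fatigue model (3CCr)

Motor units (100%, the conserved currency) occupy an active pool `Ma`, a
resting pool `Mr`, and a fatigued pool `Mf` (% MU):

    dMa/dt = C(t) - F*Ma
    dMf/dt = F*Ma - R*r*Mf
    dMr/dt = -C(t) + R*r*Mf

The feedback controller matches `Ma` to the target load TL (% of maximum):
`C = TL - Ma` when the resting reserve suffices, `C = Mr` when it does
not, and `C = TL - Ma < 0` (de-recruitment) when `Ma > TL`; at the
boundary `Ma = TL` both expressions give `C = 0`.  The rest multiplier is
`r = 1` whenever `TL > 0` and `r = r_rest >= 1` when `TL = 0`, switching
instantaneously at protocol boundaries.

These flows conserve `Ma + Mr + Mf` exactly.  (Some published statements
of the model drain the active pool with `R` instead of `F` and recover
with `R*Mf` in one equation but `R*r*Mf` in another; that combination
breaks the conservation the model itself asserts, so the
conservation-consistent form above is implemented.)

Integration is fixed-step classical RK4, default `dt = 0.01 s`, with a
guard per step that clips negative occupancies and renormalizes the sum to
100 — the guard corrects only floating-point drift (conservation holds to
1e-6 over 10^4 steps in the test suite).  All rates are per second.

Useful closed forms: residual capacity is `100 - Mf`; under sustained
maximal demand it converges to the endurance asymptote
`100/(F/R + 1)` %.  The fatigue-resistant (group A) fiber coefficients
`F = 0.004 /s, R = 0.01 /s, r = 1` are chosen so a sustained maximal
effort loses roughly a quarter of its capacity in two minutes (the RK4
value is 23.1% at 120 s; quoted design targets round this to 25%) and
recovery after rest completes within a few minutes.

**Fatigue-modified ceiling.**  Fatigue affects only the contractile term:
the instantaneous maximal force becomes

    F_max = (f_l f_v (100 - Mf)/100 + f_PE) * F0M * cos(alpha)

so a fully fatigued muscle still exerts its passive force.

## Load sharing

At each instant the net elbow flexion torque `Q` must be produced by the
muscle forces through the signed moment arms `J_i` (flexors positive):

    minimize  sum_i (w_i F_i)^2
    subject to  sum_i J_i F_i = Q,   F_min_i <= F_i <= F_max_i

Unit weights give the classical minimum-sum-of-squares criterion; setting
`w_i` to each muscle's fatigue coefficient `F_i` (dimensionless multiplier
— units cancel in the argmin) yields the fiber-type recruitment criterion:
fatigue-resistant fibers are cheap and therefore recruited first, a
compact expression of the Henneman size principle.  The reported objective
uses the weight-inside-the-square form.

With a single equality constraint the KKT conditions solve the QP exactly:
`F_i(lam) = clip(lam J_i/(2 w_i^2), F_min_i, F_max_i)` with the multiplier
found by a bracketed scalar root find on the (monotone) achieved torque —
deterministic and accurate to machine precision, verified against the
Lagrange closed form and dense grid enumeration.  When the demand exceeds
the reachable torque the bound-clamped maximal-torque solution is returned
and the deficit is surfaced as `torque_residual`; no residual "hand of
God" actuator is ever added, so capacity violations remain visible in the
output instead of being absorbed.  Antagonists under a pure flexion demand
sit at their passive minimum (their `F_min` enters the equality constraint
as a variable that is tight at its bound, not as a pre-subtracted
constant).

## Model variants

* **7M** — the individual-muscle model (toy default: 4 flexors, 3
  extensors, mirroring a triceps-three-head / biceps-two-head /
  brachioradialis / brachialis composition).
* **2M** — one condensed flexor and extensor actuator: per side, `l0M`,
  `lST`, `alpha0`, the fatigue coefficients and the geometry tables are
  arithmetic means (geometry averaged pointwise on the shared angle grid);
  `F0M` is the sum.
* **14M** — each muscle split into fiber groups sharing its geometry.  The
  split fraction comes from the percentage force decay of a sustained
  maximal calibration effort: 90% of `%decay` is attributed to the
  fast-fatigable group B, so `F0M_B = F0M * 0.9 %decay / 100` and
  `F0M_A = F0M - F0M_B`.  (Read as fractions — the literal percent product
  would multiply total force by 100 — so the pair conserves `F0M`
  exactly.)  Group B recovery is fixed at `R_B = 0.001 /s`, reflecting
  anaerobic type IIx metabolism; `F_B` and `r_B` are subject-fitted.
  Whether the A/B force distribution should differ per muscle is open;
  one shared distribution is the default and per-muscle values are
  accepted.

## The coupled session loop

Per time step: (1) fatigue-modified ceilings from the current compartment
states; (2) load sharing for the demanded torque; (3) per-muscle
activations by the inverse Hill map, **relative to the fatigued ceiling**
(a = 1 means all currently recruitable units active — the alternative,
percent of rested maximum, would under-drive fatigued muscle and is noted
as a sensitivity, not implemented); (4) each muscle's `TL_i = 100 a_i`
advances its compartment state to the next instant.  The one-step explicit
lag (activations of step k drive fatigue across [t_k, t_k+1)) avoids an
implicit coupled solve; at `dt = 0.01 s` the lag error is negligible
relative to the fatigue time constants (hundreds of seconds).

Protocol segments: `rest` (TL = 0, rest multiplier active), `mvc`
(agonists forced to TL = 100 regardless of the load-sharing solution —
maximal efforts bypass the redundancy problem — while the available
maximal moment is recorded), `static_hold` (constant torque through the
full loop; failure logged at the first instant the available maximal
moment crosses the demand, linearly interpolated inside the step), and
`curl_set` (per-sample torque and kinematics from a motion source).
Torque deficits during curls are carried as residuals and the simulation
continues.  Cycle-end markers enable equilibrium detection: the session is
flagged equilibrated when every muscle's `Mf` changes by less than
0.01 %MU between consecutive cycle ends — cyclic work/rest schedules
either reach this fatigue/recovery balance or `Mf` keeps growing.

## Calibration

* **Length scaling.**  `l0M` and `lST` scale per muscle by the ratio of
  the subject's outstretched-arm musculotendon length to the reference
  model's.
* **Condensed-actuator F0.**  During a flexion MVC (flexors fully active,
  extensors passive) the measured peak moment, corrected by the model's
  extensor passive moment, divided by the mean flexor arm and mean
  `(f_l f_v + f_PE)` gives the condensed actuator's maximal force; with
  accurate geometry this estimate is posture-independent.  A "static"
  variant omits the physiological factor.
* **Moment-arm scale k1.**  Arm profiles are recalibrated as
  `J*(phi) = k1 (J(phi) - J(0)) + J(0)`, anchored at full extension so the
  parameter reshapes the arm's angular variation rather than its overall
  scale.  k1 minimizes the *coefficient of variation* of the F0 estimates
  across postures: the raw SD is degenerate under this family (large k1
  shrinks every estimate and the SD toward zero without making the
  geometry more consistent), whereas the relative spread is
  scale-invariant and vanishes exactly when the estimates agree.  A guard
  keeps k1 = 1 whenever the optimized value would increase the raw SD, so
  recalibration never worsens the spread.  The same k1 applies to every
  muscle's arm.  On synthetic data with a known injected variation factor
  c the procedure recovers `k1 = 1/c` to better than 1%.
* **Maximal-force scale k2.**  `k2(t) = Q(t)/Q_max,flex(t)` pointwise over
  a measured MVC trace; `max_t k2` rescales every muscle's `F0M`
  (extensors included, sharing the flexor scale), after which the model
  can just reproduce the measured maximum — idempotent by construction.
* **Fatigue-parameter fitting.**  Bounded least squares
  (`F, R in [1e-5, 1] /s`, `r_rest in [1, 50]`, tolerances 1e-8, fixed
  initial guesses — deterministic) of the simulated residual capacity
  (TL = 100 during efforts, 0 during rests) to normalized MVC force
  traces: a long to-failure effort identifies `F`; a short probe effort
  after a rest identifies `R` and `r_rest` (individually they are weakly
  identified from a short probe — the well-identified quantity is close to
  the product `R r_rest` — which is why fitting uses the gauge's full
  100 Hz record, bin-averaged for speed, rather than sparse subsamples).
  The group-B variant freezes `R_B = 0.001 /s`, simulates the group-A
  share with the fixed group-A coefficients, and fits `(F_B, r_B)` on the
  share-weighted sum; it refuses to fit when the group-B share is zero
  (unidentifiable).
* **%decay.**  `100 (peak - final)/peak` with the peak taken as the
  maximum of a 0.5 s rolling mean and the final value as the last 0.5 s
  mean — a concrete operational definition chosen because sustained-MVC
  plateaus are noisy; the windowing biases a linearly decaying trace by
  under a percentage point.

## Synthetic data

The generator supplies everything the pipeline consumes, as pure functions
of parameters and a seed:

* **Toy elbow models** are built backwards from smooth moment-arm
  profiles (flexor arms peaking mid-flexion, extensor arms negative and
  flatter), with `lMT` integrated from `-J` so the geometry consistency
  constraint (`J = -d lMT/d phi` to 2%) holds by construction.  Muscle
  constants are drawn from adult-elbow ranges (`F0M` 200–800 N, `l0M`
  8–16 cm, arms scaled to `l0M` so normalized fiber lengths stay within
  0.4–1.6 over the 0–150 deg range).
* **Curl kinematics** follow a raised cosine between the range endpoints;
  the torque is the planar rigid-body result
  `Q = (I_f + m_d L^2) phidd + (m_f d_f + m_d L) g sin(phi)` with gravity
  peaking at the horizontal forearm.  Default inertial parameters describe
  an adult forearm (1.8 kg, COM at 18 cm, hand/load at 33 cm,
  0.065 kg m^2).
* **MVC gauge traces** decay along the forward 3CCr capacity at TL = 100
  with the subject's true parameters plus i.i.d. Gaussian noise (the real
  gauge record is simply "noisy"; no richer noise model is claimed).  The
  default subject truth `F = 0.01, R = 0.005, r_rest = 15` sits in the
  mid-range of reported joint-level coefficients.  Post-activation
  potentiation is deliberately not emulated: calibration protocols exclude
  the first MVC precisely to avoid it.
* **The benchmark session** is a baseline MVC triplet (8 s / to-failure /
  6 s with 15 s rests), then 3 cycles of 3 x 10 hammer curls with 90 s
  rests and an MVC triplet after each cycle — 9 curl sets and 4 MVC blocks
  — with the dumbbell at 65% of the subject's rested capacity at the
  50 deg MVC posture.

What passing tests on this synthetic data do **not** show: agreement with
any real subject's absolute forces (curve-shape and geometry choices shift
them), real EMG/force variability structure (noise here is white),
potentiation, or central fatigue.

## Problem sizes and numerical choices

Test and acceptance runs use reduced problem sizes chosen to exercise
every code path at comfortable runtimes: toy models of 2–7 muscles
(14 after splitting), holds of tens of seconds to a few minutes,
4-cycle work/rest schedules, and `dt` of 0.01–0.05 s for coupled sessions
(the fatigue time constants, 1/F and 1/R, are hundreds of seconds, so
these steps resolve the dynamics; the RK4 step passes a dt-halving
self-consistency check at 1e-9).  Ties in the load-sharing solver cannot
occur (the dual is strictly monotone where it matters); muscle ordering is
fixed by the model file.  Degenerate inputs (slack-tendon geometry, zero
moment arms, zero denominators, non-monotone time stamps) raise errors
naming the offending muscle, posture or file field.

## Known limitations

Planar single-joint torque only (no 3-D multibody inverse dynamics, no
marker processing); rigid tendon; no activation dynamics, potentiation,
history-dependent force, or central-fatigue/fourth-compartment
extensions; co-contraction beyond passive antagonist force is not
represented by the minimum-effort criteria; EMG preprocessing implements
the Butterworth-equivalent envelope (an SSA plug-in point exists but SSA
itself is not implemented).
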