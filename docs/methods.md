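# Methods

`graspaff` simulates the development of grasp affordances in the primate
parieto-premotor system. A kinematic 22-DOF arm/hand interacts with
primitive objects; parietal population codes describe each object; a
reward-modulated self-organizing map (the model AIP) compresses those codes
into an affordance representation; dynamic neural fields in model premotor
areas select reach and grasp parameters from it; a non-neural primary-motor
module executes the movement; and a scalar reinforcement signal derived
from grasp stability trains both the map and the premotor projections.
This note records the model equations as implemented, the free parameters
and how their defaults were chosen, the deliberate simplifications, and
what the synthetic protocol does and does not establish.

## Arm and hand

The arm has a 3-DOF ball shoulder (angles θ1 about x, θ2 about y, θ3 about
z), a hinge elbow (θ4) and a 3-DOF wrist; four fingers carry three flexion
hinges each and the thumb a 2-DOF base plus one hinge (22 DOFs total).
Link lengths default to l1 = l2 = 0.17 m, scaled from macaque limb
proportions for a ~7.5 kg animal; hand segment lengths are listed in
`HandConfig`. The wrist position has the closed form

    w = A(θ1,θ2,θ3)·(l1 + sin θ4 · l2) + B(θ1,θ2,θ3)·cos θ4 · l2

with orthonormal A, B (see `kinematics.py`); the analytic 3×4 Jacobian is
the exact derivative of this chain and is verified against finite
differences to 1e-5 over a thousand random postures. Inverse kinematics is
resolved-rate: θ̂ = θ + J⁺·Δx with the right pseudo-inverse
J⁺ = Jᵀ(JJᵀ)⁻¹, a per-step displacement cap (2 cm) and clamping to joint
limits; near-singular poses (e.g. the fully outstretched arm, θ4 = π/2)
raise a singularity error and the controller holds its previous targets.
Joints track their targets through PD control, τ = p(θ̂−θ) − d·θ̇, applied
to unit-inertia double integrators at the control step. The damping sign
is dissipative; gains (arm p = 400, d = 40; fingers p = 900, d = 60) give
critically-damped settling in ~0.2 s.

## Environment surrogate

Rigid-body dynamics, friction and gravity are not simulated. The learning
loop consumes exactly two physics outputs — contact events and a grasp
stability verdict — and both are produced geometrically:

* **Contacts.** Twelve hand landmarks (palm patch, four fingertip pads,
  four inner-finger midpoints, the radial side of the index distal
  phalanx, thumb pad, thumb side) are tested against the object's signed
  distance field; a landmark within 5 mm of the surface that is not
  retracting is a contact.
* **Stability.** A grasp is stable iff two contacts from opposing body
  parts (thumb–finger, thumb–inner, palm–finger, palm–inner) define a
  segment passing through the object interior, and such an opposition axis
  persists continuously for 2 s of simulation time. This is the same
  opposition-axis criterion the learning loop is rewarded on.
* **Collisions.** A landmark penetrating deeper than 4 mm while the hand
  moves faster than 0.1 m/s, without an opposing grasp configuration,
  displaces the object along the push direction by 5× the penetration
  (capped at 2 cm per step) — the kinematic stand-in for knocking the
  object out of reach. Objects are otherwise pose-fixed (gravity off,
  object suspended).

The surrogate reproduces the *reward structure* of a physics engine, not
its trajectories; absolute success rates are therefore not comparable
against a dynamics simulation, only their qualitative time course is.

## Objects and trial statistics

Training presents five primitives — cube, rectangular prism, cylinder,
sphere, flat plate — each with a fixed canonical size
(`CANONICAL_SIZES`), at uniformly random positions (distance 0.15–0.28 m,
within the encoder ranges and the arm workspace) and orientations
(intrinsic x-y-z Euler angles in ±1.2 rad). The training set is thus a
fixed object set seen under varying viewpoints, which is what makes shape
a decodable category: with sizes also randomized, cube/sphere and
cylinder/prism size distributions coincide and no code of these features
can separate them. The novel-object probe keeps the shapes but rescales
every size dimension by a uniform factor in [0.70, 0.95] and places
objects beyond the training distance range — disjoint from the training
set by construction.

## Parietal population codes

All encoders are Gaussian population codes on regular preferred-value
grids, summed over object components, with additive Gaussian noise
(sd 0.01) clipped at zero:

| code | dims | grid | range | σ | drives |
|------|------|------|-------|---|--------|
| DIST | 1 | 31 | 0–1 m | 0.05 m | F2 only |
| DIR  | 2 | 21×21 | azimuth 0–π, elevation −π–0 | 0.10 rad | F2 and AIP |
| CYL  | 3 | 9³ | ±π/2 per Euler component | 0.25 rad | AIP |
| RECT | 3 | 9³ | ±π/2 | 0.25 rad | AIP |
| SOS  | 3 | 9³ | normal components ±1 | 0.12 | AIP |
| S    | 3 | 11³ | 0–0.18 m | 0.016 m | AIP |

CYL responds only to cylinders, RECT and SOS only to box-like shapes
(spheres drive neither); the non-matching population carries pure noise.
SOS sums over the visible faces, a face being visible iff its outward
normal has negative dot product with the view direction (by default the
direction from the origin to the object). The affordance-map input **I**
concatenates DIR, CYL, RECT, SOS and S — distance is deliberately
excluded — and is normalized to unit Euclidean norm.

The widths and grid sizes above are package defaults, not published
values. They were calibrated jointly so that (i) the map input separates
the five training shapes (narrow size tuning relative to the spacing of
the canonical sizes; SOS mass small enough not to swamp the size label,
since cube/prism/plate produce identical SOS/RECT patterns at equal
orientation), and (ii) the position code decodes to ~1 cm, commensurate
with object sizes (the original coarse 15-cell grids produced ~7 cm reach
errors that made most grasps unreachable). Angular ranges are treated as
bounded intervals without wraparound; objects are sampled strictly inside
them.

## Affordance map (AIP)

A 40×40 **toroidal** self-organizing map over I. Unit activity is the
plain dot product W(i,j)·I plus noise. Learning moves the best-matching
unit (Euclidean metric, ties to the lowest flat index) and its toroidal
neighborhood toward I:

    W ← W + Θ(β; r)·α·(I − W),   Θ = exp(−β²/2r²) for β < r, else 0
    r(T) = r0·e^(−T/λ) + max(rs, 0),   α(T) = α0·e^(−T/λ) + max(rs, 0)

with the epoch T incremented once per trial and rs the global
reinforcement signal; a positive rs transiently widens the neighborhood
and raises the learning rate so that rewarded inputs recruit more units.
The rs term is floored at zero: a failed grasp decays learning back to the
schedule rather than inverting the update.

Defaults r0 = 28 (the full torus; the maximal toroidal index distance is
≈28.3), λ = 350 trials, α0 = 0.6, weights initialized U(0, 0.01). λ is
denominated in trials, so the global scale factor divides it along with
the stage lengths: a desk-scale run anneals its map within its shortened
pretraining stage instead of never leaving the global phase. This
schedule makes the first ~500 trials a genuinely global ordering phase —
every unit tracks the input mean and the map stays moderately selective —
after which the shrinking neighborhood specializes units locally, with a
learning rate still large enough to matter. Both properties are required
by the published phenomenology (an all-moderate start and a ~80 % highly
shape-selective map by the end of the ~1000-trial visual pretraining
stage); a slow decay (λ on the order of thousands of trials) never anneals
within pretraining and produces no selectivity at all.

## Premotor fields

Every premotor population is a dynamic neural field of leaky integrators,

    τ du/dt = −u + h + IN + f∗W + ε,   f = 1/(1 + e^(−β(u−u0)))

with τ = 10 ms, h = −1, β = 4, u0 = 0.5, integrated by explicit Euler at
1 ms. The interaction kernel is a Gaussian peak on a uniform inhibitory
floor, defined on a grid twice the field size so that every unit inhibits
every other (w_excite = 1.2, w_inhibit = 0.5, σ = 2 cells). Because the
kernel covers the field, the recurrent term is computed exactly as a
separable Gaussian convolution plus global inhibition proportional to the
total firing. The excitatory part is boundary-corrected (scaled by the
ratio of full to locally available kernel mass): without the correction,
border units receive systematically less recurrent support and every
winner-take-all bump collapses toward the grid center, which silently
removes most of the wrist-orientation and reach-offset space from the
model's repertoire.

Field layout: F2 direction (21×21, matching DIR) and distance (31) fields
driven by fixed 3·I relays from DIR/DIST; F7 offset-direction (21×21 over
azimuth 0–π, elevation ±π) and offset-radius (31 over 0–10 cm) fields; four
F5 aperture fields (11 units over [0,1]), one per virtual-finger
combination, each inhibiting the others with the fixed coefficient 0.25;
and a 9³ wrist-rotation field over the wrist joint ranges. Each region has
a preparation and an execution field joined by a fixed 2·I relay; every
execution field receives tonic inhibition GP = 10 until the go signal sets
it to 0. The affordance drive onto F7/F5/WR is divisively normalized
(L1) before a gain of 72: the premotor input scale then does not depend on
how sparse the map's activity has become, so field ignition survives the
map's own training. Learned weights start at U(0, 0.05).

**Reinforcement.** All afferents of the preparation fields from the map
(and F2→F7, F7→WR, F5→WR) learn ΔW = α·rs·pre⊗exec with the
execution-field firing as the eligibility trace — Hebbian for rs > 0,
anti-Hebbian for rs < 0 — applied once per reward step (the last five
control steps of a trial). Weights are floored at 0 and capped at 0.3.
The cap prevents the runaway growth that otherwise saturates a field into
an undecodable blob; the floor plus a moderate failure magnitude
(DA_fail = −0.05 against DA_success = 1) prevents the converse failure
mode, in which early failures erase the small random initialization and
permanently extinguish all drive. Learning rates default to 0.05. The
exploration/exploitation balance lives in exactly these two knobs plus the
field noise: the anti-Hebbian term erodes a failing plan's bias within a
few repeats of the same object so an alternative can win the next race,
while a rewarded plan's bias (one success shifts the relevant field input
by several units) replays reliably. Stronger failure signals (−0.1 and
beyond) tip the system into collective extinction; weaker ones (−0.02)
leave it stuck replaying whatever arbitrary plan the initial weights
favored.

## Motor control

The primary-motor module is deliberately non-neural. After a 50 ms
settling window following the go signal, each execution field is decoded
by thresholded center of mass (ξ = 0.01); if any required field has no
super-threshold unit the trial proceeds without movement. The decoded
plan holds the shoulder-centered object center (spherical), an
object-centered reach offset expressed in the world-aligned frame, a wrist
orientation, a virtual-finger combination (the F5 field with the highest
peak; exact ties go to precision < tripod < power < side) and a maximum
aperture in [0,1].

The reach controller drives the wrist along a DMP trajectory

    v̇ = uK(Σψᵢ(u)(cᵢ+x₀)/Σψᵢ(u) − x) + (1−u)K(g−x) − Dv,  u̇ = −αᵤu

with K = 100, D = 20 (critically damped), ten Gaussian phase basis
functions, equilibrium points at the goal (straight-line reaching — the
path-shaping capacity is unused), a 0.8 m/s velocity cap and αᵤ = 3.07 so
u < 0.01 at the nominal 1.5 s movement duration. The wrist first targets
center+offset; on arrival it retargets the object center; palm or thumb
contact halts the reach permanently at the current position. The grasp
controller starts the preshape as soon as the plan is decoded, and the
enclose phase when the wrist comes within κ = 6 cm of the object or on
palm contact, whichever is first. Normalized timing DMPs (0→1, 0.7 s
preshape, 0.5 s enclose) interpolate the finger joints from their current
angles to the posture table in `DEFAULT_POSTURES`; the aperture parameter
linearly scales the opening of the involved digits, and each digit
freezes at its current angles when it touches the object. The posture
table was hand-tuned so that every combination can produce a stable grasp
of at least one object class, and the preshape postures keep the fingers
moderately curled so that the palm, not the fingertips, leads the
approach (straight fingers strike first, knock the object away and make
palm contact — the trigger for both the wrist-stage reward and the
enclose phase — geometrically rare). The table is configuration-exposed.

## Trial protocol and curriculum

A trial lasts 5 s at a 1 ms base control step (the global `scale` factor
divides stage lengths and multiplies the step; `--scale 10` gives 5 ms).
The object appears at 0.5 s, the go signal at 1 s, reward in the last five
steps. Objects refresh every 6 trials. Stages:

1. **Map pretraining** (1000 trials): no movements, rs = 0, only the map
   learns.
2. **Wrist pretraining** (2000 trials): rs = DA_success/4 if any palm
   contact occurred; only the F7→wrist-rotation weights learn. The stage
   stops early when the palm-contact rate exceeds 60 % over a trailing
   window.
3. **Grasp training** (10,000 trials): rs = DA_success for a stable grasp,
   DA_fail otherwise; the map and all learned premotor weights update.
   Halfway through, the novel-object probe replaces the sampler.

Reward accounting is exact: the per-trial rs sum is one of
{5·DA_success, 5·DA_fail, 5·DA_success/4, 0}.

Within a trial the neural and motor timelines are partially decoupled for
speed: the object is encoded once at onset (it is static; noise is drawn
once), the preparation fields settle for 120 Euler steps on that constant
input, and after the go signal only the execution fields are advanced
(the between-field wiring is feedforward, so this is exact, not an
approximation). The movement then runs on the control clock.

## Analyses

The preference index of a unit over n categories is
PI = (n − Σrᵢ/r_pref)/(n−1), computed from mean settled map activities
(with the noise that was present) in 500-trial blocks; units are highly
(PI > 0.75), moderately (0.25 ≤ PI ≤ 0.75) or non- (PI < 0.25) selective.
Continuous features (direction, orientation, size components) are
discretized into five equal-width bins over their sampled range for the
per-feature PI panel. The linear feature fit regresses each unit's
activity on z-scored object features (shape as dummies) by ordinary least
squares, dropping collinear columns by rank-revealing QR. Success curves
are blocked success fractions, reported separately for familiar and novel
trials. All analyses are pure functions of the trial log.

## Problem sizes used in the shipped checks

The packaged test-suite and the reproduction script run the map
pretraining at its full length (1000 trials) and the sensorimotor stages
at `scale 10` (100 + 200 + 1000 trials, 5 ms control step), which keeps a
full run in the tens of minutes on one core while preserving the
qualitative results; the stage lengths at scale 1 match the published
protocol.

## What the synthetic protocol does and does not show

The generator emulates the published study conditions: isolated primitive
objects of a fixed training set, suspended without gravity, one per
trial, with noiseless knowledge of their geometric features. Passing
tests therefore demonstrate the *mechanisms* — topology-preserving,
reward-biased affordance compression; winner-take-all parameter
selection; staged reinforcement learning of reach/grasp parameters; and
opposition-axis grasp stability under an open-loop controller. They do
not show robustness to visual feature extraction from images, cluttered
scenes, object dynamics under force closure, or feedback-based grasp
correction, all of which are outside the model. Success rates depend
quantitatively on the contact surrogate's tolerances and on the
hand-tuned posture table; only their qualitative time course (rise to a
plateau, dip and recovery on the novel-object probe) is meaningful.

## Known limitations

* The physics surrogate cannot represent slip, rolling or re-grasping;
  grasps that a dynamics engine would reject as force-unstable can pass
  the opposition test.
* Premotor selection operates on bounded parameter grids; plans at the
  range edges are biased inward by the center-of-mass decode.
* The F5 cross-inhibition (0.25) resolves virtual-finger competition only
  through ignition timing; under near-symmetric drive two fields can
  remain co-active and the decoder's deterministic tie rule picks one.
* Checkpoint portability of RNG state assumes the same NumPy bit
  generator family across runs.
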