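# Methods

`jfisim` is a reduced-order neuromuscular model of the gripping hand
built to study the jersey-finger injury mechanism: the eccentric
overload of the deep finger flexor (FDP) tendon when a closed grip is
forced open. It trades the geometric fidelity of finite-element hand
models for a transparent, fast, fully testable pipeline with the same
structure: Hill-type muscle-tendon units (MTUs) with serial elastic
tendons, moment-arm and tendon-material calibration against reference
curves, a two-stage grip-and-retraction load case, and threshold-based
injury scoring.

## Muscle-tendon unit

Each strand is a contractile element (CE) in series with an elastic
tendon (SEE) and in parallel with a passive elastic element (PEE). All
units are SI.

**Serial elastic element.** The tendon force is zero below the rest
length `l_see_0`, follows a power-law toe region up to the relative
stretch `dU_see_nll` where it carries `dF_see_0_frac * Fmax`, and is
linear above, gaining another `dF_see_0_frac * Fmax` per additional
stretch `dU_see_l`. The toe exponent `nu = dU_see_nll / dU_see_l` is
not a free parameter: it is the unique choice that makes the curve once
continuously differentiable at the transition. The linear-branch
Young's modulus is `E = (dF_see_0_frac * Fmax / dU_see_l) / CSA`; it is
invariant under common rescaling of `Fmax` and `CSA`. Two parameter
sets matter in practice: the *stiff* set (0.8 Fmax, 0.02, 0.01), which
reproduces a 2.4 GPa positional-tendon modulus at a normalization
stress of Fmax/CSA = 30 MPa, and the *generic default* set (0.4 Fmax,
0.0425, 0.017), which gives 0.7 GPa under the same normalization. The
30 MPa normalization is a package choice that ties strand CSA to
strand Fmax so these two moduli come out on the printed scale.

**Contractile element.** Bell-shaped force-length factor
`exp(-|((l_ce/l_opt)-1)/dW|^nu)` with separate ascending/descending
widths and exponents (defaults 0.57/4 and 0.14/3), and a Hill
force-velocity law: the classic hyperbola on the concentric side
(`a_rel = 0.2`, `b_rel = 2.0 1/s`, so the unloaded shortening velocity
is 10 optimal fiber lengths per second) and a saturating eccentric
branch with plateau `F_ecc = 1.5` and slope factor `S_ecc = 2` at zero
velocity. These constants are conventional Hill-model values; none of
them is fitted here and all are configurable.

**Parallel elastic element.** Power-law spring engaging above
`L_pee_0 * l_opt` and reaching `F_pee * Fmax` at `(1 + dW_desc) *
l_opt`. The default slack length is `L_pee_0 = 1.0`: the PEE engages
exactly at the optimal fiber length. This choice is deliberate — the
initialization below places every fiber *at* its optimal length with
the tendon at rest, and a PEE that is already stretched there would
preload the whole hand with ~20 % of Fmax of passive force, closing it
far more than "slightly" and inflating the passive activation
effectiveness by an order of magnitude.

**Activation dynamics.** First-order filter with asymmetric time
constants (10 ms activation, 40 ms deactivation) and a floor
`a_min = 0.005`; the update uses the exact exponential step so results
do not depend on the integrator. Calcium-kinetics (Hatze-type)
activation is out of scope.

**Contraction dynamics.** The fiber velocity solves the series force
balance `F_CE(v_ce) + F_PEE = F_SEE + d_se (v_mtu - v_ce)` at each
step. The serial damping element (default `d_se = 0.2 * Fmax` N·s/m
per strand) makes the residual strictly increasing in `v_ce`, so the
root is unique even when the elastic force exceeds the eccentric
plateau — the situation that necessarily occurs during violent rod
retraction at low activation. The public solver brackets the root at
±20 optimal lengths/s and expands if needed; the simulation engine uses
a vectorized safeguarded-Newton iteration over all strands and is
tested against the bracketed solver.

**Initialization.** At the initial posture every strand satisfies
`c_ef * l_mtu_i = l_ce_opt + l_see_0` with `c_ef = 1.05` for flexors
and 0.95 for extensors, representing their stretched or compressed
state in the straightened hand. The scale factor is implemented as a
constant offset on the effective MTU length, so at t = 0 the fiber sits
exactly at its optimum and the tendon exactly at its rest length (zero
force). With the minimum activation this equilibrium lets the hand
close slightly on its own, which is the intended neutral-posture
behavior. Whole-muscle maximum forces are split evenly over parallel
strands (`Fmax_s = Fmax_T / n_s`), one strand per digit.

## Hand model

Digits 2-5 are planar chains of three rigid phalanges behind a fixed
metacarpal, with revolute MCP/PIP/DIP joints (flexion positive, palmar
side negative y, straight finger at q = 0). Joints carry passive
stiffness (0.01 N·m/rad), damping (0.002 N·m·s/rad) and a one-sided
range-of-motion penalty (5 N·m/rad beyond 0-90°/0-100°/0-80°). These
passive values are stand-ins of plausible magnitude, chosen once for
stable quasi-static gripping; they are config-overridable. Segment
masses come from a 0.35 kg/m linear density. The planar reduction is
justified by the revolute-joint kinematics of the target system: with
hinge joints, finger motion is flexion-plane by construction, and
requiring via points to lie in the plane through the joint center
normal to the hinge axis is automatic in 2D.

Muscles are polylines through via points fixed in the segment frames.
Moment arms come from the tendon-excursion relation
`r_j = -dL/dq_j` (central difference, h = 1e-6 rad), which tests verify
against an analytic chord-distance oracle and against virtual-work and
excursion-integral identities. Routing: FDP runs to the distal phalanx
(crosses MCP, PIP, DIP), FDS to the middle phalanx (MCP, PIP), one
dorsal extensor per digit; with four digits this yields exactly the
20-curve flexor moment-arm topology. Forward dynamics of each chain use
the closed-form planar mass matrix and velocity-product terms and a
fixed-step RK4 integrator (default dt = 2e-5 s, stability-checked).

## Calibration

**Routing.** Model moment-arm curves are scored against reference
curves with the mean absolute error and its normalization by the mean
measured arm (NMAE, in percent); both series are resampled to a common
2° grid first. The fit moves the palmar depth (local y) of every via
point of a muscle, digits independently, pooling all curves of a digit
in one bounded trust-region least-squares problem (depth bounds keep
points on the anatomical side of the bone). The optimizer returns the
better of the initial and fitted routing, so the reported NMAE never
degrades. On noise-free references generated from a known via-point
set, all 20 curves are recovered below 1 % NMAE from ±20 % perturbed
starts.

**Tendon material.** The model stress-strain curve is
`sigma(eps) = F_SEE(eps)/CSA`. The three tendon parameters are fitted
to a reference curve by bounded least squares on the 0-3 % strain
window; the 0-5 % window is reported alongside. Internally `dU_see_l`
is parameterized as a fraction of `dU_see_nll` so the toe exponent
stays above one throughout. Because the serial element has only a toe
and an indefinite linear branch, a reference with a necking region is
matched well up to ~3 % but overestimated beyond — the 0-5 % score is
then systematically worse than the 0-3 % score, which the tests assert
on the synthetic necking reference.

## Load case

A rigid cylinder (length 100 mm, diameter 20 mm) sits in the palm
plane; an effective 5 mm skin pad is added to its radius for contact.
Stage 1 (0-100 ms): flexors receive a step neural input (filtered by
the activation dynamics), extensors stay at minimum activation, and the
hand closes around the rod. Contact is a penalty normal force
(2e4 N/m, 20 N·s/m) with Coulomb friction (static 0.4, dynamic 0.3).
Friction is regularized twice: the coefficient relaxes from static to
dynamic over a 5 mm/s sliding scale, and the force is capped by a
viscous branch (100 N·s/m) near sticking so its force-velocity slope
stays bounded — a pure steep regularization produces stick-slip chatter
under explicit integration. At 80 ms a tied coupling (5e3 N/m) pins
every contacting point to the rod so the contact reaction cannot shake
the grip loose; a tie releases permanently once stretched beyond 5 mm.
Stage 2 (100-200 ms): the rod is driven kinematically, ramping linearly
over 1 ms to 11.615 m/s along a palm-diagonal direction, forcing the
fingers open; rod dynamics are not solved. Gravity is off (the forearm
is considered fully constrained).

Within each step the skeleton is advanced by a coupled RK4 derivative:
contact and tie forces are recomputed at every substate, and the muscle
force follows its tendon-stiffness linearization
`F = F0 + k_see * dL(path)` around the step's start (moment arms and
fiber length frozen within the step). The fiber and activation states
advance once per step (operator splitting). This treatment keeps the
stiff force elements inside the RK4 scheme; with it the gripped hand
settles to a quasi-static balance with net joint torques below
1e-3 N·m, which the test suite asserts at the end of the no-retraction
hold.

The protocol runs eight retraction simulations at activations
0/20/40/60/70/80/90/100 % plus a model check at 100 % without
retraction. For each run the activation effectiveness
`eta_a = mean(per-strand grip-phase peak force) / mean(Fmax)` is
computed over the flexor strands, and every flexor strand is scored
with the injury criteria. Everything is deterministic given the
configuration; there are no stochastic elements in the load case.

## Injury criteria

* **Avulsion**: peak tendon force at or above 105.91 N — the lowest
  reported FDP-insertion avulsion load (10.8 kg) converted with
  standard gravity (9.80665 m/s²; rounding happens only at reporting).
  Applied per strand, since the underlying experiment loaded single
  insertions.
* **Tendon strain (TSIC)**: severity graded by peak engineering strain
  on the tendon rest length — minor at 4 %, major at 8 %, rupture at
  10 %, matching the strain-hardening / necking / failure stages of a
  positional tendon's stress-strain curve. Crossings are inclusive
  (≥), the conservative reading.
* **Muscle strain (MSIC)**: same grading semantics applied to the CE
  strain `l_ce/l_opt - 1`. No default thresholds are shipped — the
  published values live in a source this package does not reproduce —
  so the criterion reports "not evaluated" unless thresholds are
  supplied in the configuration.

## Synthetic reference data

No redistributable dataset exists for the three calibration inputs, so
the package generates surrogates with controlled structure:

* **Moment-arm curves**: smooth low-order polynomials in joint angle
  around literature-scale means (FDP-MCP anchored at 9.7 mm, optional
  2.0 mm noise), per-digit scale factors, 20-curve topology.
* **Tendon stress-strain**: piecewise toe (power law), linear region
  with configurable modulus (default 2.4 GPa), optional necking with a
  reduced tangent modulus; continuous everywhere. With necking
  disabled the curve lies exactly in the serial-element model family,
  giving a round-trip identity test for the tendon fit.
* **Hand fixture**: digits 2-5 with FDP/FDS/extensor strands. The
  whole-muscle forces (FDP 360 N, FDS 320 N, extensor 80 N, each split
  over four strands) and fiber lengths are *synthetic* stand-ins of
  plausible magnitude, not measured values. Noise is additive and
  independent per sample; all generators are bit-reproducible given
  spec and seed.

What passing tests show — and what they do not: the pipeline's
mechanics, calibration machinery and criteria behave correctly and
reproduce the qualitative injury phenomenology (grip force rises with
activation; injuries appear only at high activation; they are
avulsions, not strain injuries; a maximal grip without retraction is
injury-free). Absolute forces and the exact activation level at which
the first avulsion appears depend on the synthetic muscle parameters
and would shift with subject-specific data.

## Numerical choices and limitations

* dt = 2e-5 s fixed-step RK4; protocol runs cover 0.2 s (10,000 steps)
  for four digits and 12 strands. Results are recorded at 12.5 kHz.
* Contraction root solve: tolerance 1e-10 m/s (bracketed) or residual
  below 1e-9·Fmax (vectorized Newton); fiber length floored at
  0.2·l_opt as a divergence guard.
* Routing/tendon fits: `scipy.optimize.least_squares` (trf), ftol/xtol
  1e-10 or tighter, forward differences.
* Degenerate inputs raise: slack lengths ≤ 0 at initialization,
  non-positive segment lengths, coincident via points, empty series,
  unordered thresholds.
* Not modeled: finger pulleys, joint capsules, soft-tissue volumes,
  3D abduction, tendon creep/fatigue/plasticity, rod dynamics,
  inter-digit coupling, jersey fabric (the rod is the standard
  surrogate). The tendon model has no failure branch, so stresses are
  overestimated beyond ~4 % strain; with the stiff calibration the
  simulated strains stay below that range.
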