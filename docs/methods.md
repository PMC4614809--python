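# Methods

## Model and frames

The limb is two rigid segments: a static pelvis whose frame coincides with
the global frame, and a femur connected by a purely rotational
three-degree-of-freedom hip. Global axes: x̂ craniocaudal, ŷ proximodistal
(the femur's long axis points along −ŷ in the neutral posture), ẑ
mediolateral. Femur-fixed coordinates are stored relative to the hip joint
center in the neutral-posture frame, so posing the femur is a pure
rotation about the center — no translations, matching a ball-joint hip.

Muscles are ordered polylines of attachment/via points, each rigidly owned
by one segment; the first point is pelvis-owned, the last femur-owned.
Wrapping surfaces are out of scope: a path is valid only while it stays
clear of the joint region (see the generator notes below).

## Joint angles and axis conventions

A posture is the angle triple (θ_fe, θ_abd, θ_lar) in degrees with
anatomical sign semantics: positive = extension, adduction, lateral
rotation. Geometric handedness is carried separately by per-dof sense
flags s ∈ {+1, −1} on the joint, so a left-limb model flips the ABD and
LAR senses instead of redefining the anatomical signs. The conventional
"10° of abduction" starting posture is therefore stored as
`abd_deg = −10`.

Femur orientation is the intrinsic cascade

    R(q) = Rz(s_fe θ_fe) · Rx(s_abd θ_abd) · Ry(s_lar θ_lar).

The **corrected** instantaneous axes follow the joint-coordinate-system
structure of that cascade:

    u_fe  = ẑ                                  (pelvis-fixed, never moves)
    u_abd = Rz(s_fe θ_fe) · x̂                  (moves with FE only)
    u_lar = Rz(s_fe θ_fe) · Rx(s_abd θ_abd) · ŷ (moves with FE and ABD)

Long-axis rotation moves no axis: the femur spins about u_lar itself.
These axes are exactly the hinge directions for which a small rotation
about u_dof through the joint center equals perturbing the corresponding
cascade angle while holding the other two fixed — so the "pure hinge"
experimental construction and the partial derivative of the cascade agree
identically, not just approximately.

The **legacy** mode returns the neutral axes (ẑ, x̂, ŷ) at every posture:
the historical pelvis-fixed-axes error, kept as a first-class mode so the
error can be measured (`diff_modes`). The two modes coincide at neutral
for all dofs, everywhere for FE, and for ABD whenever θ_fe = 0; these
coincidences are asserted in the test suite.

## Moment arms

Both routes implement r = −∂L/∂θ (virtual work: positive moment arm ⇒ the
muscle shortens as the anatomical angle increases ⇒ it drives extension /
adduction / lateral rotation; negative ⇒ flexion / abduction / medial
rotation).

* **Tendon excursion**: central difference
  r = −(L(q+h) − L(q−h)) / (2h), where the perturbation rotates the femur
  (and its path points) by ±h about u_dof through the joint center.
  Default half-step h = 0.25°, bounded to (0, 2]; at 0.25° the
  second-order truncation error on realistic geometry is below
  10⁻⁵ femur lengths while staying ~6 orders above double-precision
  cancellation noise. Halving h shrinks the residual ≈4×, as the suite
  verifies.
* **Geometric lever** (the reference): only pelvis↔femur path segments
  change length with posture (same-segment segments are rigid), and for a
  segment with femur-owned endpoint b, other endpoint a, unit direction
  ê = (b−a)/|b−a| and joint center c,

      r = Σ −s_dof · u_dof · ((b − c) × ê),

  exact with no differencing. The excursion route is retained because it
  is the classical procedure; the geometric route is the oracle every
  excursion value is tested against.

Zero-length path segments at an evaluated posture raise a
`DegenerateGeometryError` rather than being skipped: a collapsing segment
means the geometry left the model's domain of validity.

## Sweep protocol, classification, group statistics

The default sweep holds 10° of abduction and zero long-axis rotation and
steps flexion-extension in 15° increments; the FE range is model-specific
and defaults to −90°..+90° (configurable — the published per-taxon ranges
varied). Records carry raw and femur-length-normalized moment arms;
normalization makes taxa of different sizes comparable and every
classification decision scale-invariant.

`classify_function` labels each muscle × dof over the sweep: `negligible`
if max |r_norm| < ε (default ε = 0.005 femur lengths — the literature says
"weak" without a threshold, so a configurable default is provided);
otherwise `switching` if the sign changes between adjacent grid postures
(crossing angle linearly interpolated between the bracketing pair; an
exact grid zero counts as a crossing at that posture); otherwise
obligatory with the sign held throughout. The stated categories are not
exhaustive (all values one sign but some inside ±ε); the implementation
resolves such cases to the obligatory label of the held sign, since no
crossing exists and the muscle is not negligible.

`summarize_groups` splits each muscle's normalized moment arm by sign *per
posture* — summed positive side vs summed negative-side magnitude — rather
than summing fixed functional rosters, because group membership is
posture-dependent (muscles switch polarity). Sweep means average the same
signed parts over all muscle × posture cells with equal weights (the
source analyses state no weighting). `compare_cohorts` contrasts cohorts
(e.g. bipeds vs quadrupeds) with between-model means ± sample SD per
posture plus cohort means of per-model sweep means; no hypothesis testing
is attempted — the comparisons in this literature are descriptive.

## Synthetic models

`make_hinge_toy` builds the two-link validation toy: origin at distance a
(pelvis) and insertion at distance b (femur) on opposite sides of the
joint in the plane normal to the tested dof's neutral axis, giving the
closed-form moment arm a·b·sinθ/√(a²+b²+2ab·cosθ) and length
√(a²+b²+2ab·cosθ).

`make_hip_model` draws a 19-muscle model using the standard archosaur hip
nomenclature. Nominal attachment regions (units of femur length) place
each muscle in its anatomically plausible neighbourhood — iliofemoral
origins dorsal, caudofemoral caudal, puboischiofemoral cranio-/
caudoventral, insertions on the femoral shaft — jittered uniformly by
±0.05. The names carry nomenclature only; the geometry is generated, not a
reconstruction of any published taxon. Three generator rules matter:

* **Determinism**: one `numpy` PCG64 stream per seed; identical specs
  yield byte-identical model files (generator id `hip-synth-1`).
* **Joint clearance**: every pelvis→femur segment must stay ≥ 0.20 femur
  lengths long over the working posture range (FE −90°..90°, abduction 0°
  and 10°), enforced by deterministic rejection-resampling. Shorter
  grazing segments are where a real muscle would wrap around bone, which
  the polyline path model deliberately excludes; they are also where the
  moment-arm curve's curvature explodes and a fixed-step excursion
  estimate stops being meaningful.
* **Polarity targets**: an optional map muscle → dof → sign asks the
  generator to place the muscle so its *neutral-posture* moment arm has
  that sign (with a 10⁻³ femur-length margin), achieved by mirroring the
  origin/insertion across coordinate planes through the joint center;
  unsatisfiable targets raise an error naming muscle and dof.
  Posture-dependent switches away from neutral are left free to emerge —
  they are a real phenomenon, not a defect.

What the generator does **not** emulate: real bone geometry and wrapping,
taxon-specific attachment positions, muscle architecture (PCSA, fiber
length), or multi-joint paths. Passing tests on these models therefore
validates the *engine* — conventions, calculus, bookkeeping — not any
biological conclusion about a particular taxon.

## Numerical choices

* Elementary rotations are right-handed about the stated axis; arbitrary-
  axis rotations use the Rodrigues form. Orthonormality and det = +1 hold
  to 10⁻¹² across the full posture range (asserted property).
* Angles are degrees in every file and public interface, radians only
  internally.
* Record tables are CSV with 17-significant-digit floats (exact double
  round trip); model files are sorted-key JSON (or YAML), so equal models
  serialize byte-identically. Unknown file keys warn, they do not fail;
  an unknown schema version fails.
* Tie-breaks: `classify_function` reports the *first* crossing when a
  curve crosses zero more than once; `diff_modes` reports the posture
  attaining the per-dof maximum |Δ| via a deterministic argmax.

## Problem sizes

The validation suite and acceptance script run the hinge toy over
θ ∈ [−150°, 150°] (1° steps), the oracle comparison over 100 seeded
19-muscle models × 13 postures × 3 dofs × both modes (148,200 paired
evaluations), the axis-rule check over 1,000 random postures, and the
remaining properties over 3–10 seeded models each — sizes at which every
closed-form and cross-route comparison is exercised densely.

## Known limitations

* Hip only: no knee/ankle chains, so two-joint muscles are represented
  only by their hip-crossing geometry.
* Straight-line polylines with rigid via points; no wrapping surfaces or
  path solvers, hence the generator's clearance rule.
* Moment arms only — no forces, activations or torques.
* The corrected convention fixes the axis definition; it cannot recover
  the published per-taxon curves, which depend on unpublished model
  geometries.
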