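# hipmoment

Three-degree-of-freedom hip joint axes and tendon-excursion muscle moment
arms for two-segment (pelvis + femur) limb models.

## The problem

Comparative musculoskeletal models of archosaur hindlimbs estimate muscle
*moment arms* — the effective lever r = −∂L/∂θ of a muscle-tendon unit of
length L about a joint angle θ — to infer muscle function (extensor vs
flexor, abductor vs adductor, lateral vs medial rotator) across taxa and
postures. Several published analyses specified all three hip rotation axes
relative to the static pelvis. That is correct only for flexion-extension
(FE): anatomically, the abduction-adduction (ABD) and long-axis rotation
(LAR) axes must travel with the femur as the hip flexes and abducts.
Pelvis-fixed ABD/LAR axes therefore yield moment arms about functionally
wrong axes at any non-neutral posture.

`hipmoment` is a reusable engine for this corrected convention. It
computes, classifies and compares 3D hip muscle moment arms under

* **corrected** axes — a joint coordinate system: the FE axis stays on the
  pelvis z axis; the ABD axis is the FE-rotated x axis; the LAR axis is the
  FE- and ABD-rotated y axis (long-axis rotation moves no axis); and
* **legacy** axes — all three axes pelvis-fixed, retained deliberately so
  the size and structure of the historical error can be quantified
  (`diff_modes`).

Femur orientation is the intrinsic cascade
`R = Rz(s_fe·θ_fe) · Rx(s_abd·θ_abd) · Ry(s_lar·θ_lar)`, with anatomical
sign semantics (positive θ = extension / adduction / lateral rotation) and
per-dof sense flags so left and right limbs share one convention. Moment
arms follow the virtual-work sign: positive = extensor / adductor /
lateral rotator.

Two independent routes compute every moment arm:

* the **tendon-excursion method** — central differencing of muscle length
  under a small pure-hinge rotation about the instantaneous axis, the
  procedure used by the modelling studies; and
* the **geometric lever** — the exact projection `−s·u·((b−c)×ê)` summed
  over pelvis→femur path segments, which serves as the engine's internal
  oracle.

## Worked example

The analytic two-link toy (origin and insertion one unit either side of
the joint in the FE plane) has the exact moment arm
`a·b·sinθ / √(a²+b²+2ab·cosθ)`:

```python
import hipmoment as hm

toy = hm.make_hinge_toy(hm.ToySpec(a=1.0, b=1.0, dof="FE"))
for fe in (30, 60, 90):
    p = hm.Posture(fe, 0, 0)
    print(f"FE={fe:3d}  excursion={hm.excursion_moment_arm(toy,'toy','FE',p):.6f}"
          f"  geometric={hm.geometric_moment_arm(toy,'toy','FE',p):.6f}"
          f"  closed-form={hm.hinge_toy_moment_arm(1,1,fe):.6f}")
```

```
FE= 30  excursion=0.258819  geometric=0.258819  closed-form=0.258819
FE= 60  excursion=0.500000  geometric=0.500000  closed-form=0.500000
FE= 90  excursion=0.707106  geometric=0.707107  closed-form=0.707107
```

At 60° the lever is exactly 0.5 model units; the excursion and geometric
routes agree to the 4·10⁻⁷ truncation error of the 0.25° half-step.

Sweeping a seeded synthetic archosaur-hip model (19 muscles with the
standard nomenclature) under both conventions and differencing the modes:

```python
model = hm.make_hip_model(hm.SynthSpec(seed=0))
records = hm.run_sweep(model, hm.SweepProtocol(modes=("corrected", "legacy")))
diff, summary = hm.diff_modes(records)
print(summary.to_string(index=False))
```

```
dof  fe_deg  abd_deg  lar_deg  max_abs_delta_norm
ABD    90.0    -10.0      0.0            0.268590
 FE   -90.0    -10.0      0.0            0.000000
LAR    90.0    -10.0      0.0            0.256086
```

The FE moment arms are identical between conventions at every posture (the
FE axis was never wrong), while the ABD and LAR errors grow with hip
extension, here reaching ~0.27 femur lengths. Classification of the same
sweep labels this model's CFB `switching` about ABD with a sign crossing
at FE ≈ 17.7° — an abductor at flexed postures and an adductor at extended
ones, the polarity-switch behaviour that makes posture-resolved signed
group sums (rather than fixed muscle rosters) necessary.

The same pipeline is scriptable from the shell:

```
hipmoment synth --kind hip --seed 0 -o hip.json
hipmoment sweep hip.json -o corrected.csv              # corrected mode (default)
hipmoment sweep hip.json --mode both -o records.csv    # both conventions
hipmoment classify corrected.csv -o labels.csv
hipmoment summarize corrected.csv -o summary.csv       # one model x mode per table
hipmoment diff records.csv -o diff.csv
hipmoment frames hip.json -o axes.csv
```

## Layout

* `hipmoment.model` — domain types, validation, model/record file I/O
* `hipmoment.kinematics` — axis conventions and rigid femur transforms
* `hipmoment.momentarm` — tendon-excursion and geometric moment arms
* `hipmoment.sweep` — sweeps, classification, group statistics, contrasts
* `hipmoment.synthetic` — analytic toys and seeded random hip models
* `hipmoment.cli` — the `hipmoment` command

See `docs/methods.md` for the model conventions, numerical choices and
limitations.
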