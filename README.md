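# fsukin

Systematic motion parametrization for Functional Spinal Units (FSUs): a small
Python library and command-line tool for robotic and in-vitro spine
biomechanics.

An FSU — two adjacent vertebrae plus the intervening disc and ligaments — is
the smallest physiological motion segment of the spine.  Loading experiments
(spinal loading simulators, instrumented intraoperative probes, robotic
devices) need an unambiguous joint coordinate system (JCS) to command pure
bendings and translations and to interpret the measured loads.  In scoliotic
spines the vertebrae are skewed and asymmetric, and the segment's rest pose
can shift by millimetres and tens of degrees between the preoperative (supine
CT) and intraoperative (prone C-arm CT) configurations, so "the same" 5°
flexion can mean different things depending on how and when the JCS was
defined.  `fsukin` makes every ingredient of that definition explicit and
quantifies the consequences of each choice.

## What it computes

**Vertebral frames from six landmarks.**  For each vertebra, with P1/P2 the
centres of the cranial/caudal endplates and P3–P6 the high/low points of the
right and left cranial pedicles, the frame origin is the endplate-centre
midpoint and the axes follow the Panjabi convention (X left, Y cephalad,
Z anterior):

    e_Y = a/‖a‖,  e_Z ∝ (b/‖b‖) × e_Y,  e_X = e_Y × e_Z,
    a = P2→P1,    b = ½(P3→P5 + P4→P6).

**A virtual 6-DoF intervertebral joint.**  The measured relative pose
`_V2·T_V1` of the cranial (V2) to the caudal (V1) vertebra at a chosen
reference time is split into two static transforms around a joint frame A
placed midway between the endplates bounding the intervertebral space.  All
subsequent motion is carried by six joint coordinates
θ = (x, y, z, α, β, γ) — translations in mm, rotations composed as
`Rz(γ)·Ry(β)·Rx(α)` in degrees — which are identically zero at the reference
configuration and read as the physiological motion directions
(compression, flexion/extension, axial rotation, lateral bending).

**Two JCS orientation policies.**  *Single parent* copies the caudal
vertebra's axes (`_V1·R_A = I`); *double parent* interpolates halfway between
both vertebral orientations by quaternion SLERP — equivalently
`R_const² = _V1·R_V2` via the rotation square root.

**Dissimilarity analyses.**  Given a preoperative reference and an observed
intraoperative pose, the package builds PO- and IO-referenced joints, applies
identical single-axis motions from the same equilibrium, and reports where
the cranial vertebra ends up under each (‖Δr‖ in mm, geodesic rotation
distance ΔR in degrees, and percentages against the IO outcome).  It also
maps single-axis joint loads to the wrench a pedicle-screw-mounted device at
mounting frame M2 must deliver, through the adjoint of `_M2·T_A`
(`Ad(T) = [[R, p̂R], [0, R]]`, lever arms in metres so torques come out in
Nm), and compares the PO/IO requirements (‖ΔF‖, ‖Δτ‖).

Key exact properties the test suite pins down: under the single-parent
policy, PO- and IO-referenced joints share axis directions, so pure
translations produce *identical* final poses, pure bendings produce *zero*
rotation dissimilarity (position dissimilarity follows the lever-arm law
2·sin(δ/2)·d⊥) and *zero* required-wrench dissimilarity.

## Worked example

Generate a synthetic scoliotic FSU (skewed, asymmetric vertebrae; a 3 mm /
20° rest-pose shift of the cranial vertebra), measure the shift, and sweep
single-axis motions:

```sh
fsukin synth --out demo --seed 7 --translation-mm 3 --rotation-deg 20
fsukin shift --caudal demo/caudal_landmarks.fcsv \
             --cranial demo/cranial_landmarks.fcsv \
             --io-transform demo/io_transform.json
```

```json
{
  "delta_r_mm": 3.0000000000000053,
  "delta_R_deg": 20.0,
  "pct_r": 11.618279657533883
}
```

The pose-shift metrics recover the generated ground truth exactly: the
cranial vertebra sits 3 mm / 20° away from its preoperative pose, a shift of
~11.6 % of the intervertebral distance.

```sh
fsukin sweep --caudal demo/caudal_landmarks.fcsv \
             --cranial demo/cranial_landmarks.fcsv \
             --io-transform demo/io_transform.json --out demo/results
```

Flexion/extension rows of `demo/results/motion_dissimilarity_single.csv`:

```text
 axis  magnitude  delta_r_mm  delta_R_deg    pct_r
alpha        -15    0.447226            0 1.737013
alpha        -10    0.298625            0 1.156591
alpha         -5    0.149455            0 0.578290
alpha          5    0.149455            0 0.580386
alpha         10    0.298625            0 1.165007
alpha         15    0.447226            0 1.756062
```

Reading: commanding the same flexion on the PO-referenced and the
IO-referenced single-parent joint displaces the cranial vertebra by up to
0.45 mm (growing as the chord 2·sin(δ/2) of the bend angle, about the ~1.7 mm
joint-origin offset the rest-pose shift induced) while the resulting
orientations agree exactly — the 0.00° rotation column.  `fsukin wrench`
produces the corresponding required-wrench tables at the mounting frame, and
`fsukin icp` fits intraoperative to preoperative vertebra meshes when the IO
transform has to be estimated from segmentations.

## Layout

| module | contents |
| --- | --- |
| `fsukin.geometry` | rotations, rigid transforms, Euler Z-Y-X, SLERP, rotation square roots, geodesic distance |
| `fsukin.frames` | landmark sets, `f_coord`, vertebral and mounting frames |
| `fsukin.joint` | FSU references, joint construction/splitting, forward/inverse kinematics, single-axis motions, pose-shift metrics |
| `fsukin.wrench` | wrenches, skew/adjoint, required-wrench mapping, wrench dissimilarity |
| `fsukin.experiments` | motion and wrench dissimilarity sweeps, summaries |
| `fsukin.synthetic` | deterministic synthetic FSU generator and rest-pose shifts |
| `fsukin.io`, `fsukin.icp`, `fsukin.cli` | Slicer FCSV / markups JSON / CSV landmark files, 4×4 transforms, result CSVs, config, the ICP adapter, the `fsukin` CLI |

See `docs/methods.md` for the model, conventions, parameter defaults and
known limitations.
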