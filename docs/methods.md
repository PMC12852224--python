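# Methods

This note documents the model behind `fsukin`, the conventions and defaults
it commits to, what the synthetic data generator does and does not emulate,
and the numerical choices that matter.

## Rigid-body model

Both vertebrae of a functional spinal unit (FSU) are treated as rigid bodies:
vertebral deformation during loading is neglected, which is the standard
assumption for bone at physiological loads.  Every pose is a proper rigid
transform acting on homogeneous column vectors by left multiplication;
geometry is carried in millimetres, public angles in degrees, forces in N and
torques in Nm.

## Vertebral frames

Each vertebra is registered by six landmarks confined to the vertebral body
and pedicles: endplate centres P1 (cranial) and P2 (caudal), and the high/low
points of the right (P3/P4) and left (P5/P6) cranial pedicles.  Posterior
elements are deliberately excluded — they deform in scoliosis and are altered
by surgical dissection, whereas the body and pedicles are comparatively
stable.  The frame origin is the midpoint of the endplate centres; the axes
come from `f_coord(origin, a, b)` with `a = P2→P1` and
`b = ½(P3→P5 + P4→P6)`:

* `e_Y = a/‖a‖` — cephalad, exactly along the endplate axis;
* `e_Z ∝ (b/‖b‖) × e_Y` — anterior;
* `e_X = e_Y × e_Z` — left.

On a skewed vertebra `a` and `b` are not perpendicular, so the cross product
is normalized before completing the triad; the construction demands at least
1° between `a` and `b` and raises otherwise.  Because only landmark geometry
enters, the construction is equivariant under rigid motion: moving the
vertebra moves its frame by exactly the same transform.  This is what makes
the preoperative and intraoperative frames comparable.

## The intervertebral joint

Let V1 (caudal) and V2 (cranial) be the vertebral frames and
`T_rel = _V2·T_V1` their measured relative pose at the chosen reference time
(preoperative, PO, or intraoperative, IO).  A joint frame A is placed at the
midpoint of the two endplate centres bounding the intervertebral space — the
caudal vertebra's P1 and the cranial vertebra's P2.  (The alternative
reading, the midpoint of the two *outer* endplate centres, is selectable via
`origin_convention="outer"`; the bounding-endplate placement is the default
because those are the surfaces that enclose the disc space the joint is meant
to represent.)

`T_rel` is split into two static transforms, `T_rel = split_V2_A ∘
split_A_V1`, with A riding rigidly on V1 and its twin A′ (coincident with A
at reference) riding on V2.  Joint orientation follows one of two policies:

* **Single parent** — A copies V1's axes: `_V1·R_A = I` exactly.  The
  identity block is stored bitwise, which is what makes several invariances
  below hold to the last ulp rather than to a tolerance.
* **Double parent** — A's axes interpolate between V1's and V2's by
  quaternion SLERP at ratio r (default 0.5).  At r = 0.5 the offset rotation
  is the principal square root of `_V1·R_V2`; the suite verifies the
  SLERP-midpoint and square-root constructions agree to 1e-9.  A half-turn
  relative rotation has no unique midpoint and raises.

All motion is carried by six joint coordinates θ = (x, y, z, α, β, γ),
zero at the reference configuration.  The joint matrix is
`[Rz(γ)·Ry(β)·Rx(α) | (x, y, z)]`, read as the pose of A′ in A, so positive
coordinates move the cranial vertebra along the positive joint axes — the
physiological sign convention (cephalad +y, flexion +α, axial rotation +β,
lateral bending +γ).  In the chain
`_V2·T_V1(θ) = split_V2_A ∘ (_A'·T_A)(θ) ∘ split_A_V1` the middle factor is
therefore the joint matrix's inverse.  Coordinate extraction inverts the
chain and decomposes the rotation in the Z-Y-X convention; at |β| = 90° the
decomposition is degenerate, the convention γ := 0 is applied and the result
carries a `gimbal_degenerate` flag (physiological axial rotations are far
below 90°, but the library stays total).

## Commanding motion from a displaced equilibrium

The interesting case is a joint referenced at PO while the segment now rests
at IO.  Two conventions are implemented for "apply +δ about one axis from the
equilibrium pose":

* **increment** (default): compose a pure screw of magnitude δ about the
  joint frame's axis through the joint origin, evaluated at the equilibrium
  configuration, V1 held fixed.  Algebraically the conjugation of the
  single-axis joint matrix by `split_A_V1`, right-applied to the equilibrium
  pose.
* **parameter**: extract θ at the equilibrium, add δ to the named component,
  recompose.  Retained for reconciliation; at large equilibrium angles the
  Euler recomposition mixes axes and the two conventions diverge.

Both reduce to the plain forward pose when the equilibrium *is* the joint's
own reference pose.  The increment convention is the default because it is
the only one under which the single-parent PO/IO comparisons produce the
exact invariances below.

### Exact single-parent invariances

Because PO- and IO-referenced single-parent joints share axis directions
(both equal V1's axes) and differ only in origin:

* pure translations from the same equilibrium produce bitwise-identical
  final poses;
* pure bendings produce exactly zero orientation dissimilarity, and their
  position dissimilarity follows the lever-arm law
  `‖Δr‖ = 2·sin(δ/2)·‖d⊥‖`, with d⊥ the joint-origin offset perpendicular to
  the bend axis;
* pure bendings produce exactly zero required-wrench dissimilarity at the
  mounting frame.

The suite asserts all three on 100 seeded synthetic FSUs with rest-pose
shifts of ~3 mm and 15–28°.

### Sign symmetry

+δ and −δ commands give equal dissimilarity norms wherever the screw pair is
a mirror image: all single-parent motions, all rotation dissimilarities, and
double-parent translations (linear in the command).  Double-parent *bending
position* dissimilarity is genuinely sign-dependent under the increment
convention — the PO and IO joints bend about axes tilted against each other
by half the rest-pose shift rotation, and the even and odd parts of the
outcome difference do not cancel; on the default fixtures the ±10°
difference is of order 10 %.  Any same-equilibrium pair of δ-rotations also
bounds the double-parent rotation dissimilarity by 2δ.

## Pose and wrench dissimilarity metrics

Pose shift between two relative poses: ‖Δr‖ is the Euclidean distance
between the pose translations; ΔR is the geodesic distance between the
rotations, the rotation angle of `R1·R2ᵀ` (the arccos-of-trace formula,
evaluated as `atan2(‖skew part‖, (trace−1)/2)`, which is the same angle but
exact at zero and robust where the arccos argument grazes ±1).  Sweep
outcomes are compared in the caudal-vertebra frame (positions of the cranial
frame origin), and percentages are taken against the IO-referenced outcome's
relative-position norm; percentages with a zero reference are reported as
NaN, never as zero.

A wrench stacks force and torque, `(F; τ)`.  The wrench a device mounted at
the cranial mounting frame M2 must deliver to realise `w_A` at the joint is
`w_M2 = Ad(_M2·T_A)ᵀ·w_A` with `Ad(T) = [[R, p̂R], [0, R]]` and p in metres
(the mm→m conversion lives inside the adjoint so torques cannot silently come
out a factor 1000 off).  This "literal" direction is the table-reproduction
default; the mathematically standard covector transform
`Ad(_A·T_M2)ᵀ·w_A`, under which the wrench–twist power pairing is
frame-invariant, is available as `convention="power"`, and the two are
adjoint inverses of each other.  Force/torque dissimilarities are Euclidean
norms of the PO/IO difference with percentages against the IO wrench norms.

## Mounting frames

Pedicle-screw entry points plus a screw offset define where a loading device
attaches.  The mount origin is the entry-pair midpoint offset by
`(0, −h_screw, 0)` in the vertebra frame, with h_screw = 25 mm by default
(the minimal offset of the pedicle screws the loading scenario assumes).
Mount axes come from `f_coord` with the half inter-mount vector
`c = ½·M1→M2` (negated for M2, which faces M1) and the half right-to-left
entry vector of the respective vertebra.  Everything is evaluated once in the
reference configuration and frozen as a rigid attachment to the vertebra — a
configuration-dependent device frame would not be rigid.

## Synthetic data generator

`fsukin.synthetic` builds two stacked parametric vertebrae: default geometry
loosely mid-thoracic (22 mm body height, 15 mm pedicle lateral offset, 10 mm
posterior offset, 5 mm intervertebral gap, 32 mm entry-point span), with
per-vertebra rigid skew angles and a left–right asymmetry factor that
scales the pedicle offsets, emulating scoliotic shape imbalance.  The
preoperative-to-intraoperative shift rotates the cranial vertebra about a
(seeded) random axis through the caudal origin and translates it; with that
pivot the pose-shift metrics recover the commanded magnitudes exactly for
any axis direction, which is what makes the generator its own ground truth.
Default shift magnitudes (3 mm, 20°) sit in the range observed between
supine and prone imaging of scoliotic segments; the acceptance script uses
the two studied segments' magnitudes (3.02 mm / 15.26°, 3.19 mm / 28.34°)
verbatim.

What the generator does **not** emulate: real endplate curvature and
landmark-picking ambiguity (only isotropic Gaussian jitter via
`perturb_landmarks`), segmentation/registration error of intraoperative
imaging, soft-tissue mechanics, and any load-to-displacement relation — the
package parametrizes motion and maps loads, it does not model stiffness.
Passing tests therefore demonstrate the kinematic and static conventions,
not fidelity to any particular patient's anatomy.

## File formats and spaces

Landmarks are read/written as 3D Slicer FCSV, markups JSON, or plain CSV,
with labels carrying the roles (P1…P6, PedR/PedL).  The internal coordinate
space is LPS; files declaring RAS are sign-flipped on the first two axes at
the boundary.  Transforms are 4×4 homogeneous matrices (JSON or whitespace
text, translation in mm); a rotation block with orthonormality drift above
1e-6 is re-orthonormalized with a warning, and anything non-rigid beyond
1e-3 (or with a negative determinant) is rejected.  Result CSVs have a fixed
column set and fixed float formatting, so identical configurations produce
byte-identical files; undefined percentages serialize as `NaN`.

## Registration adapter

When the intraoperative relative pose must be estimated from segmented
meshes, `fsukin.icp.fit_icp` wraps `trimesh.registration.icp` (rigid: no
scale, no reflection) over surface point samples of both meshes.  Settings
map as: `inlier_ratio` → fraction of the per-repeat surface samples used
(each repeat re-draws its sample, which is also what makes repeats differ),
`tolerance_interval_mm[0]` → convergence threshold, `max_iterations` → cap.
Repeat-to-repeat spread is reported against the first repeat rather than
hidden.  The adapter is validated by ground-truth recovery of a known rigid
move on synthetic meshes (sub-millimetre, ~1–2° with point sampling); its
run-to-run spread is registration-implementation-dependent and is not an
accepted quantity.

## Numerical choices

* Rotation validity: orthonormality and det +1 to 1e-8 on input, preserved
  to 1e-10 under composition (property-tested).
* Quaternions live on the canonical hemisphere (w ≥ 0); SLERP takes the
  shorter arc and raises on antipodal orientations (no unique geodesic).
* Rotation square roots are defined for angles strictly below 180° and raise
  at a half turn (no unique root).
* The single-parent identity block, elementary screws and their conjugations
  are grouped so that identity products stay bitwise exact; this is why the
  "identical final pose" and "0.00°" statements are exact equalities in the
  suite, not toleranced approximations.
* Gimbal lock (|β| = 90°): γ := 0, flag set, re-synthesis still reproduces
  the input rotation.

## Known limitations

* Two-vertebra segments only; no poly-segmental chains.
* No stiffness or soft-tissue model: wrenches are mapped, not predicted.
* The double-parent PO/IO bending comparison depends on the
  motion-application convention; the increment convention documented here is
  self-consistent but other conventions (e.g. parameter-space increments at
  a displaced equilibrium) give different rotation dissimilarities, and both
  are exposed for reconciliation against other implementations.
* The ICP adapter trades the exact mesh-distance correspondence for point
  sampling (keeping the dependency footprint small); for low-resolution or
  fractured intraoperative meshes its repeatability, like any ICP's, is
  limited.
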