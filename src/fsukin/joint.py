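"""The intervertebral reference frame and the virtual 6-DoF joint.

A functional spinal unit (FSU) is modelled as two rigid vertebrae, caudal V1
and cranial V2, joined by a virtual joint at a reference frame A placed in the
intervertebral space.  The measured relative pose ``T_rel = _V2 T_V1`` at the
chosen reference time (preoperative PO or intraoperative IO) is split into two
static transforms,

    ``T_rel = split_V2_A ∘ split_A_V1``,

with A riding rigidly on V1 and its twin A' (coincident at reference) riding
on V2.  All subsequent motion lives in the joint transform between A and A':
three prismatic coordinates (x, y, z, mm) and three revolute coordinates
(alpha, beta, gamma, degrees) composed as ``Rz(gamma) Ry(beta) Rx(alpha)``.
At the reference configuration all six coordinates are identically zero.

Two joint-frame orientation policies exist.  *Single parent* copies the caudal
vertebra's axes (the de-facto standard of spinal loading rigs).  *Double
parent* interpolates between both vertebral orientations by quaternion SLERP
(ratio 0.5 by default), equivalently the rotation square root of the relative
rotation — a definition meant to be fairer to strongly skewed scoliotic
segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .frames import Frame, LandmarkSet, build_vertebra_frame
from .geometry import (
    PoseDissimilarity,
    RigidTransform,
    UnitQuaternion,
    euler_zyx_rotation,
    pose_dissimilarity,
    rotation_to_euler_zyx,
    slerp,
)

__all__ = [
    "JOINT_AXES",
    "FsuReference",
    "JointCoordinates",
    "JointDefinition",
    "ParentMode",
    "apply_single_axis_motion",
    "build_joint",
    "case_vertebra_shift",
    "extract_coordinates",
    "forward_pose",
    "joint_transform",
    "shift_reference",
]

#: Joint coordinate order: prismatic x, y, z (mm), revolute alpha, beta, gamma (deg).
JOINT_AXES = ("x", "y", "z", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class JointCoordinates:
    """The six joint parameters: translations in mm, rotations in degrees.

    ``gimbal_degenerate`` is set on extraction when |beta| = 90 deg made the
    Euler decomposition non-unique (gamma := 0 convention applied)."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    gimbal_degenerate: bool = False

    def __post_init__(self) -> None:
        for axis in JOINT_AXES:
            if not math.isfinite(getattr(self, axis)):
                raise ValueError(f"joint coordinate {axis} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, axis) for axis in JOINT_AXES])

    @classmethod
    def from_array(cls, values: np.ndarray, *, gimbal_degenerate: bool = False) -> "JointCoordinates":
        v = np.asarray(values, dtype=float).reshape(6)
        return cls(*v, gimbal_degenerate=gimbal_degenerate)

    def incremented(self, axis: str, magnitude: float) -> "JointCoordinates":
        if axis not in JOINT_AXES:
            raise ValueError(f"unknown joint axis {axis!r}; expected one of {JOINT_AXES}")
        return replace(self, **{axis: getattr(self, axis) + magnitude})


@dataclass(frozen=True)
class ParentMode:
    """Joint-frame orientation policy: 'single' (caudal axes) or 'double'
    (SLERP between both vertebral orientations at ``ratio``)."""

    kind: str = "single"
    ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("single", "double"):
            raise ValueError("parent mode must be 'single' or 'double'")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("interpolation ratio must lie in [0, 1]")


@dataclass(frozen=True)
class FsuReference:
    """An FSU configuration at a reference time: the two vertebral frames,
    their landmark sets and the measured relative pose ``_V2 T_V1``."""

    caudal: Frame
    cranial: Frame
    relative: RigidTransform
    ref_tag: str = "PO"
    caudal_landmarks: LandmarkSet | None = None
    cranial_landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        recomputed = self.cranial.as_transform().inverse() @ self.caudal.as_transform()
        if not (
            np.allclose(recomputed.rotation, self.relative.rotation, atol=1e-9)
            and np.allclose(recomputed.translation, self.relative.translation, atol=1e-9)
        ):
            raise ValueError("relative transform is inconsistent with the vertebral frames")

    @classmethod
    def from_landmarks(
        cls,
        caudal_landmarks: LandmarkSet,
        cranial_landmarks: LandmarkSet,
        *,
        ref_tag: str = "PO",
    ) -> "FsuReference":
        caudal = build_vertebra_frame(caudal_landmarks, name="V1")
        cranial = build_vertebra_frame(cranial_landmarks, name="V2")
        relative = cranial.as_transform().inverse() @ caudal.as_transform()
        return cls(caudal, cranial, relative, ref_tag, caudal_landmarks, cranial_landmarks)


@dataclass(frozen=True)
class JointDefinition:
    """A constructed joint: frame A (world pose at reference) and the two
    static splits of the reference transform."""

    frame_A: Frame
    split_A_V1: RigidTransform
    split_V2_A: RigidTransform
    mode: ParentMode
    ref_tag: str = "PO"
    origin_convention: str = "bounding"

    @property
    def reference_pose(self) -> RigidTransform:
        """The reference relative pose, recomposed from the splits."""
        return self.split_V2_A @ self.split_A_V1


def _joint_origin(ref: FsuReference, convention: str) -> np.ndarray:
    if ref.caudal_landmarks is None or ref.cranial_landmarks is None:
        raise ValueError("joint construction needs the landmark sets of both vertebrae")
    if convention == "bounding":
        # Midpoint of the two endplate centres bounding the intervertebral
        # space: the caudal vertebra's cranial endplate (its P1) and the
        # cranial vertebra's caudal endplate (its P2).
        return 0.5 * (ref.caudal_landmarks.p1 + ref.cranial_landmarks.p2)
    if convention == "outer":
        return 0.5 * (ref.caudal_landmarks.p2 + ref.cranial_landmarks.p1)
    raise ValueError("origin_convention must be 'bounding' or 'outer'")


def build_joint(
    ref: FsuReference,
    mode: ParentMode = ParentMode(),
    *,
    origin_convention: str = "bounding",
) -> JointDefinition:
    """Place the joint frame A and split the reference transform.

    The origin sits equidistant from the two endplate centres facing the
    intervertebral space (``origin_convention='bounding'``; ``'outer'`` uses
    the far endplates instead).  Single-parent orientation equals V1's axes
    exactly; double-parent right-multiplies V1 by the SLERP fraction of the
    relative rotation, so at ratio 0.5 the frame's offset rotation squared
    reproduces ``_V1 R_V2``.  A half-turn relative rotation has no unique
    midpoint and raises.
    """
    o_a = _joint_origin(ref, origin_convention)
    r_v1 = ref.caudal.orientation
    r_v2 = ref.cranial.orientation
    o_v1 = ref.caudal.origin
    o_v2 = ref.cranial.origin

    if mode.kind == "single":
        r_a = r_v1
        rot_a_v1 = np.eye(3)  # exact by definition
    else:
        q_rel = UnitQuaternion.from_rotation(r_v1.T @ r_v2)
        r_const = slerp(UnitQuaternion.identity(), q_rel, mode.ratio).as_rotation()
        r_a = r_v1 @ r_const
        rot_a_v1 = r_const.T

    split_a_v1 = RigidTransform(rot_a_v1, r_a.T @ (o_v1 - o_a))
    split_v2_a = RigidTransform(r_v2.T @ r_a, r_v2.T @ (o_a - o_v2))
    frame_a = Frame(o_a, r_a, parent="O", name=f"A_{ref.ref_tag}")
    return JointDefinition(frame_a, split_a_v1, split_v2_a, mode, ref.ref_tag, origin_convention)


def joint_transform(theta: JointCoordinates) -> RigidTransform:
    """The joint's homogeneous transform: rotation ``Rz(gamma) Ry(beta)
    Rx(alpha)``, translation ``(x, y, z)``.  Zero coordinates give the
    identity exactly.

    This matrix is the pose of the outgoing frame A' (riding the cranial
    vertebra) expressed in the incoming frame A, so positive coordinates move
    the cranial vertebra along the positive joint axes — the physiological
    sign convention (cephalad +y, flexion +alpha, ...).  In the kinematic
    chain ``_V2 T_V1 = _V2 T_A' ∘ _A' T_A ∘ _A T_V1`` the middle factor is
    therefore this matrix's inverse.
    """
    return RigidTransform(
        euler_zyx_rotation(theta.alpha, theta.beta, theta.gamma),
        np.array([theta.x, theta.y, theta.z]),
    )


def forward_pose(jd: JointDefinition, theta: JointCoordinates) -> RigidTransform:
    """Relative pose ``_V2 T_V1`` at the given joint coordinates:
    ``split_V2_A ∘ T_joint(theta)^-1 ∘ split_A_V1`` (see
    :func:`joint_transform` for the direction of the middle factor)."""
    return jd.split_V2_A @ joint_transform(theta).inverse() @ jd.split_A_V1


def extract_coordinates(jd: JointDefinition, observed: RigidTransform) -> JointCoordinates:
    """Joint coordinates reproducing an observed relative pose ``_V2 T_V1``.

    Inverse of :func:`forward_pose`; at |beta| = 90 deg the gimbal convention
    of the Euler extraction applies and the result is flagged.
    """
    inner = (jd.split_V2_A.inverse() @ observed @ jd.split_A_V1.inverse()).inverse()
    euler = rotation_to_euler_zyx(inner.rotation)
    x, y, z = inner.translation
    return JointCoordinates(
        x, y, z, euler.alpha, euler.beta, euler.gamma,
        gimbal_degenerate=euler.gimbal_degenerate,
    )


def _screw(axis: str, magnitude: float) -> RigidTransform:
    if axis in ("x", "y", "z"):
        t = np.zeros(3)
        t["xyz".index(axis)] = magnitude
        return RigidTransform(np.eye(3), t)
    angles = {"alpha": 0.0, "beta": 0.0, "gamma": 0.0}
    angles[axis] = magnitude
    return RigidTransform(euler_zyx_rotation(**angles), np.zeros(3))


def apply_single_axis_motion(
    jd: JointDefinition,
    equilibrium: RigidTransform,
    axis: str,
    magnitude: float,
    *,
    convention: str = "increment",
) -> RigidTransform:
    """Command a single-axis motion from an equilibrium pose (typically the
    intraoperative rest pose) and return the resulting ``_V2 T_V1``.

    ``convention='increment'`` (default): compose a pure screw of the given
    magnitude about the joint frame's axis through the joint origin, both
    taken at the equilibrium configuration with V1 held fixed.  Since A rides
    V1, this is the conjugation of the elementary joint transform by
    ``split_A_V1``, right-applied to the equilibrium pose.

    ``convention='parameter'``: extract the joint coordinates at equilibrium,
    add the magnitude to the named coordinate and re-run the forward pose.

    Both conventions coincide with ``forward_pose(jd, magnitude·e_axis)``
    when the equilibrium is the joint's own reference pose.
    """
    if axis not in JOINT_AXES:
        raise ValueError(f"unknown joint axis {axis!r}; expected one of {JOINT_AXES}")
    if convention == "increment":
        # The chain's middle factor is the inverse of the joint matrix, so a
        # +magnitude screw enters as its single-axis inverse.
        s = _screw(axis, -magnitude)
        s1 = jd.split_A_V1
        # M = split_A_V1^-1 ∘ S ∘ split_A_V1, grouped so that identity blocks
        # stay exact: (R_S t1 - t1) vanishes bitwise for pure translations.
        rot = s1.rotation.T @ s.rotation @ s1.rotation
        trans = s1.rotation.T @ ((s.rotation @ s1.translation - s1.translation) + s.translation)
        return equilibrium @ RigidTransform(rot, trans)
    if convention == "parameter":
        theta = extract_coordinates(jd, equilibrium)
        return forward_pose(jd, theta.incremented(axis, magnitude))
    raise ValueError("convention must be 'increment' or 'parameter'")


def case_vertebra_shift(ref_po: FsuReference, relative_io: RigidTransform) -> PoseDissimilarity:
    """Preoperative-to-intraoperative shift of the FSU pose.

    Translation: Euclidean distance between the relative-pose translations
    (the caudal origin expressed in the cranial frame at the two times).
    Rotation: geodesic distance between the relative rotations.  Percentage:
    relative to the intraoperative translation norm.
    """
    return pose_dissimilarity(ref_po.relative, relative_io, denominator=relative_io)


def shift_reference(
    ref_po: FsuReference,
    relative_io: RigidTransform,
    *,
    ref_tag: str = "IO",
) -> FsuReference:
    """Re-reference an FSU at an observed relative pose, holding V1 fixed.

    The cranial vertebra (frame and landmarks) is carried by the rigid world
    motion that realises ``relative_io``; the caudal side is untouched.  This
    produces the intraoperative reference from the preoperative one plus a
    measured intraoperative relative transform.
    """
    if ref_po.cranial_landmarks is None:
        raise ValueError("re-referencing needs the cranial landmark set")
    t1 = ref_po.caudal.as_transform()
    t2 = ref_po.cranial.as_transform()
    t2_io = t1 @ relative_io.inverse()
    world_shift = t2_io @ t2.inverse()
    cranial_landmarks = ref_po.cranial_landmarks.transformed(world_shift)
    cranial = build_vertebra_frame(cranial_landmarks, name="V2")
    relative = cranial.as_transform().inverse() @ t1
    return FsuReference(
        ref_po.caudal,
        cranial,
        relative,
        ref_tag,
        ref_po.caudal_landmarks,
        cranial_landmarks,
    )
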