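"""Rotation and rigid-transform algebra for intervertebral kinematics.

All rotations are proper 3x3 matrices (columns orthonormal, det +1) acting on
column vectors by left multiplication; rigid transforms carry translations in
millimetres.  Angles are degrees at every public interface — the clinical
tables this package feeds report degrees — and radians only transiently inside
trigonometric kernels.

The module provides the primitives the joint parametrization is built from:
Euler Z-Y-X synthesis/extraction (with an explicit gimbal-lock convention),
quaternion SLERP with shortest-arc semantics, rotation square roots, the
geodesic distance on rotations, and the pose-dissimilarity metric used to
compare preoperative against intraoperative outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "ROTATION_TOL",
    "AntipodalRotationError",
    "HalfTurnError",
    "EulerZYX",
    "PoseDissimilarity",
    "RigidTransform",
    "UnitQuaternion",
    "assert_rotation",
    "euler_zyx_rotation",
    "geodesic_distance",
    "is_rotation",
    "pose_dissimilarity",
    "rotation_to_euler_zyx",
    "slerp",
    "sqrt_rotation",
]

#: Tolerance to which orthonormality and unit determinant are enforced.
ROTATION_TOL = 1e-8


class AntipodalRotationError(ValueError):
    """SLERP between antipodal orientations (a half turn apart): the
    interpolation axis is ambiguous and no unique geodesic exists."""


class HalfTurnError(ValueError):
    """Square root of a half-turn rotation: the root is not unique."""


def is_rotation(matrix: np.ndarray, tol: float = ROTATION_TOL) -> bool:
    """True if ``matrix`` is a proper rotation within ``tol``."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        return False
    return (
        np.allclose(m.T @ m, np.eye(3), atol=tol)
        and abs(np.linalg.det(m) - 1.0) <= max(tol, 1e-10)
    )


def assert_rotation(matrix: np.ndarray, tol: float = ROTATION_TOL, name: str = "rotation") -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if not is_rotation(m, tol):
        raise ValueError(f"{name} is not a proper rotation matrix within {tol:g}")
    return m


@dataclass(frozen=True)
class RigidTransform:
    """Homogeneous rigid transform: ``p_parent = R @ p_child + t``.

    ``rotation`` is a 3x3 proper rotation, ``translation`` a 3-vector in mm.
    Composition and inversion follow the usual left-multiplication convention
    on homogeneous column vectors.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("bottom row of a homogeneous transform must be (0, 0, 0, 1)")
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point ``(3,)`` or a stack ``(n, 3)``."""
        p = np.asarray(points, dtype=float)
        if p.ndim == 1:
            return self.rotation @ p + self.translation
        return p @ self.rotation.T + self.translation


@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion on the canonical hemisphere (w >= 0).

    The double cover of the rotation group is resolved at construction: a
    quaternion and its negation describe the same rotation, and the
    representative with non-negative scalar part is stored.
    """

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        q = np.array([self.w, self.x, self.y, self.z], dtype=float)
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"quaternion norm {norm:.6g} is not 1 within 1e-6")
        q /= norm
        if q[0] < 0.0 or (q[0] == 0.0 and _first_nonzero_sign(q[1:]) < 0.0):
            q = -q
        object.__setattr__(self, "w", float(q[0]))
        object.__setattr__(self, "x", float(q[1]))
        object.__setattr__(self, "y", float(q[2]))
        object.__setattr__(self, "z", float(q[3]))

    @classmethod
    def identity(cls) -> "UnitQuaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_rotation(cls, matrix: np.ndarray) -> "UnitQuaternion":
        x, y, z, w = _ScipyRotation.from_matrix(np.asarray(matrix, dtype=float)).as_quat()
        return cls(w, x, y, z)

    def as_rotation(self) -> np.ndarray:
        return _ScipyRotation.from_quat([self.x, self.y, self.z, self.w]).as_matrix()

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])

    def dot(self, other: "UnitQuaternion") -> float:
        return float(self.as_array() @ other.as_array())


def _first_nonzero_sign(v: np.ndarray) -> float:
    for c in v:
        if c != 0.0:
            return math.copysign(1.0, c)
    return 1.0


def euler_zyx_rotation(alpha: float, beta: float, gamma: float, *, degrees: bool = True) -> np.ndarray:
    """Compose ``Rz(gamma) @ Ry(beta) @ Rx(alpha)``.

    This is the intrinsic Z-Y-X convention of the virtual joint's three
    revolute axes: alpha about x (flexion/extension), beta about y (axial
    rotation), gamma about z (lateral bending).
    """
    for name, value in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite")
    return _ScipyRotation.from_euler("ZYX", [gamma, beta, alpha], degrees=degrees).as_matrix()


@dataclass(frozen=True)
class EulerZYX:
    """Euler angles (degrees) with a gimbal-degeneracy flag."""

    alpha: float
    beta: float
    gamma: float
    gimbal_degenerate: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


def rotation_to_euler_zyx(matrix: np.ndarray, *, degrees: bool = True) -> EulerZYX:
    """Extract (alpha, beta, gamma) with ``R = Rz(gamma) Ry(beta) Rx(alpha)``.

    beta is confined to [-90, 90].  At |beta| = 90 the decomposition is
    degenerate (gimbal lock); the convention gamma := 0 is applied, alpha
    absorbs the remaining rotation, and the result is flagged.  The
    re-synthesized rotation reproduces the input in either branch.
    """
    r = assert_rotation(matrix)
    cos_beta = math.hypot(r[0, 0], r[1, 0])
    if cos_beta > 1e-9:
        beta = math.atan2(-r[2, 0], cos_beta)
        gamma = math.atan2(r[1, 0], r[0, 0])
        alpha = math.atan2(r[2, 1], r[2, 2])
        degenerate = False
    elif r[2, 0] < 0.0:  # beta = +90
        beta = math.pi / 2.0
        gamma = 0.0
        alpha = math.atan2(r[0, 1], r[1, 1])
        degenerate = True
    else:  # beta = -90
        beta = -math.pi / 2.0
        gamma = 0.0
        alpha = math.atan2(-r[0, 1], r[1, 1])
        degenerate = True
    if degrees:
        alpha, beta, gamma = map(math.degrees, (alpha, beta, gamma))
    return EulerZYX(alpha, beta, gamma, gimbal_degenerate=degenerate)


def slerp(q_from: UnitQuaternion, q_to: UnitQuaternion, r: float) -> UnitQuaternion:
    """Spherical linear interpolation along the shorter great-circle arc.

    ``r = 0`` returns ``q_from``, ``r = 1`` returns ``q_to`` (up to the
    canonical hemisphere), ``r = 0.5`` the rotation halfway between — the
    "equal contribution" midpoint used by the double-parent joint frame.

    Raises :class:`AntipodalRotationError` when the two orientations are a
    half turn apart: the arc midpoint axis is then ambiguous.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("interpolation ratio must lie in [0, 1]")
    a = q_from.as_array()
    b = q_to.as_array()
    dot = float(a @ b)
    if dot < 0.0:  # shortest arc: flip one representative
        b = -b
        dot = -dot
    if dot < 1e-8:
        raise AntipodalRotationError(
            "orientations are a half turn apart; the interpolation axis is ambiguous"
        )
    dot = min(dot, 1.0)
    omega = math.acos(dot)
    if omega < 1e-12:
        out = a.copy()
    else:
        s = math.sin(omega)
        out = (math.sin((1.0 - r) * omega) / s) * a + (math.sin(r * omega) / s) * b
    out /= np.linalg.norm(out)
    return UnitQuaternion(*out)


def sqrt_rotation(matrix: np.ndarray) -> np.ndarray:
    """The principal square root of a rotation: same axis, half the angle.

    Defined for rotation angles strictly below 180 deg; at a half turn the
    root is not unique and :class:`HalfTurnError` is raised.
    """
    r = assert_rotation(matrix)
    rotvec = _ScipyRotation.from_matrix(r).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle >= math.pi - 1e-8:
        raise HalfTurnError("rotation angle is 180 deg; the square root is not unique")
    return _ScipyRotation.from_rotvec(rotvec / 2.0).as_matrix()


def geodesic_distance(r1: np.ndarray, r2: np.ndarray, *, degrees: bool = True) -> float:
    """Geodesic distance on the rotation group: the rotation angle of
    ``R1 @ R2.T``, i.e. ``arccos((trace(R1 @ R2.T) - 1) / 2)``.

    Evaluated as ``atan2(|skew part|, (trace - 1) / 2)`` — mathematically the
    same angle, but exact at zero and immune to the arccos branch losing
    precision when the trace argument grazes ±1.  Symmetric and bi-invariant;
    range [0, 180] deg.
    """
    a = np.asarray(r1, dtype=float)
    b = np.asarray(r2, dtype=float)
    m = a @ b.T
    cos_term = (float(np.trace(m)) - 1.0) / 2.0
    sin_term = 0.5 * math.sqrt(
        (m[2, 1] - m[1, 2]) ** 2 + (m[0, 2] - m[2, 0]) ** 2 + (m[1, 0] - m[0, 1]) ** 2
    )
    angle = math.atan2(sin_term, cos_term)
    return math.degrees(angle) if degrees else angle


@dataclass(frozen=True)
class PoseDissimilarity:
    """Origin- and orientation-wise dissimilarity between two rigid poses.

    ``percent_r`` is NaN when no reference length is available (absent or
    zero-translation denominator).
    """

    delta_r_mm: float
    delta_R_deg: float
    percent_r: float = math.nan

    def __post_init__(self) -> None:
        if self.delta_r_mm < 0.0:
            raise ValueError("delta_r_mm must be non-negative")
        if not 0.0 <= self.delta_R_deg <= 180.0:
            raise ValueError("delta_R_deg must lie in [0, 180]")


def pose_dissimilarity(
    t_a: RigidTransform,
    t_b: RigidTransform,
    denominator: RigidTransform | None = None,
) -> PoseDissimilarity:
    """Compare two poses expressed over the same frame pair.

    Translation: Euclidean distance between the two translations (mm).
    Rotation: geodesic distance between the two rotations (deg).
    ``percent_r``: 100 * delta_r over the denominator's translation norm,
    typically the intraoperative reference pose; NaN when unavailable.
    """
    delta_r = float(np.linalg.norm(t_a.translation - t_b.translation))
    delta_rot = geodesic_distance(t_a.rotation, t_b.rotation)
    percent = math.nan
    if denominator is not None:
        ref = float(np.linalg.norm(denominator.translation))
        if ref > 1e-12:
            percent = 100.0 * delta_r / ref
    return PoseDissimilarity(delta_r, delta_rot, percent)
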