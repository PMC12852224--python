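"""Wrenches and the adjoint machinery mapping intervertebral loads to the
device mounting point.

A wrench stacks force (N) and torque (Nm) as ``(F; tau)``.  Geometry is
carried in mm throughout the package; lever arms are converted to metres
inside :func:`adjoint` so that torques come out in Nm.

The mapping of a desired wrench at the joint frame A to the required wrench at
the cranial mounting frame M2 is ``w_M2 = Ad(_M2 T_A)^T w_A`` with the adjoint
block matrix ``Ad(T) = [[R, p̂ R], [0, R]]`` — the convention the loading
analysis states (''literal'', the default).  The mathematically standard
covector transform, ``w_M2 = Ad(_A T_M2)^T w_A``, which conserves the
wrench–twist power pairing, is available as ``convention='power'``; see the
methods note for the relation between the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .frames import Frame
from .geometry import RigidTransform
from .joint import JointDefinition

__all__ = [
    "AdjointMatrix",
    "Wrench",
    "WrenchDissimilarity",
    "adjoint",
    "map_twist",
    "map_wrench",
    "required_wrench",
    "skew",
    "wrench_dissimilarity",
]


@dataclass(frozen=True)
class Wrench:
    """Force (N) and torque (Nm) about the origin of a named frame."""

    force: np.ndarray
    torque: np.ndarray
    frame: str = "A"

    def __post_init__(self) -> None:
        f = np.asarray(self.force, dtype=float).reshape(3)
        t = np.asarray(self.torque, dtype=float).reshape(3)
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(t))):
            raise ValueError("wrench components must be finite")
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "torque", t)

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.force, self.torque])

    @classmethod
    def from_array(cls, values: np.ndarray, frame: str = "A") -> "Wrench":
        v = np.asarray(values, dtype=float).reshape(6)
        return cls(v[:3], v[3:], frame)


@dataclass(frozen=True)
class AdjointMatrix:
    """6x6 adjoint of a rigid transform, block form [[R, p̂R], [0, R]] with
    p in metres."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (6, 6):
            raise ValueError("adjoint must be 6x6")
        if not np.allclose(m[3:, :3], 0.0, atol=1e-12):
            raise ValueError("lower-left adjoint block must be zero")
        object.__setattr__(self, "matrix", m)


def skew(p: np.ndarray) -> np.ndarray:
    """Skew-symmetric cross-product matrix: ``skew(p) @ v == p × v``."""
    x, y, z = np.asarray(p, dtype=float).reshape(3)
    return np.array([
        [0.0, -z, y],
        [z, 0.0, -x],
        [-y, x, 0.0],
    ])


def adjoint(transform: RigidTransform) -> AdjointMatrix:
    """Adjoint of a rigid transform, with the translation (mm) converted to
    metres so that force-to-torque lever arms produce Nm."""
    r = transform.rotation
    p_m = transform.translation / 1000.0
    top = np.hstack([r, skew(p_m) @ r])
    bottom = np.hstack([np.zeros((3, 3)), r])
    return AdjointMatrix(np.vstack([top, bottom]))


def map_twist(transform: RigidTransform, twist: np.ndarray) -> np.ndarray:
    """Re-express a twist ``(v; omega)`` (m/s, rad/s) through the adjoint:
    ``Ad(T) @ twist``."""
    return adjoint(transform).matrix @ np.asarray(twist, dtype=float).reshape(6)


def map_wrench(
    t_m2_from_a: RigidTransform,
    w_a: Wrench,
    *,
    convention: str = "literal",
    out_frame: str = "M2",
) -> Wrench:
    """Map a wrench at frame A to the mounting frame.

    ``convention='literal'`` (default, used for the dissimilarity tables):
    ``Ad(_M2 T_A)^T w_A`` — forces at the joint pick up a lever-arm torque
    through the off-diagonal block.  ``convention='power'``:
    ``Ad(_A T_M2)^T w_A``, the transform under which the wrench–twist pairing
    is frame-invariant.
    """
    if convention == "literal":
        ad = adjoint(t_m2_from_a).matrix
    elif convention == "power":
        ad = adjoint(t_m2_from_a.inverse()).matrix
    else:
        raise ValueError("convention must be 'literal' or 'power'")
    return Wrench.from_array(ad.T @ w_a.as_array(), frame=out_frame)


def required_wrench(
    jd: JointDefinition,
    displaced_pose: RigidTransform,
    mounts: tuple[Frame, Frame],
    w_a: Wrench,
    *,
    convention: str = "literal",
) -> Wrench:
    """Wrench a device at mounting frame M2 must deliver to realise ``w_a``
    at the joint frame A, with the FSU at ``displaced_pose`` (``_V2 T_V1``).

    M2 rides the cranial vertebra and A the caudal one, so the chain is
    ``_M2 T_A = _M2 T_V2 ∘ _V2 T_V1 ∘ _V1 T_A`` at the displaced
    configuration.
    """
    _, m2 = mounts
    if m2.parent != "V2":
        raise ValueError("the second mounting frame must be attached to V2")
    t_m2_a = m2.as_transform().inverse() @ displaced_pose @ jd.split_A_V1.inverse()
    return map_wrench(t_m2_a, w_a, convention=convention)


@dataclass(frozen=True)
class WrenchDissimilarity:
    """Force/torque dissimilarity norms with percentages relative to the
    intraoperative-condition wrench; NaN marks an undefined percentage
    (zero reference norm, e.g. no force in pure bending)."""

    delta_F_N: float
    delta_tau_Nm: float
    percent_F: float = math.nan
    percent_tau: float = math.nan

    def __post_init__(self) -> None:
        if self.delta_F_N < 0.0 or self.delta_tau_Nm < 0.0:
            raise ValueError("dissimilarity norms must be non-negative")


def wrench_dissimilarity(w_po: Wrench, w_io: Wrench) -> WrenchDissimilarity:
    """Euclidean force and torque dissimilarities between the wrenches under
    the preoperative- and intraoperative-referenced joints, in the same
    frame.  Percentages are taken against the IO wrench norms."""
    if w_po.frame != w_io.frame:
        raise ValueError(f"wrench frames differ: {w_po.frame!r} vs {w_io.frame!r}")
    delta_f = float(np.linalg.norm(w_io.force - w_po.force))
    delta_tau = float(np.linalg.norm(w_io.torque - w_po.torque))
    ref_f = float(np.linalg.norm(w_io.force))
    ref_tau = float(np.linalg.norm(w_io.torque))
    pct_f = 100.0 * delta_f / ref_f if ref_f > 1e-12 else math.nan
    pct_tau = 100.0 * delta_tau / ref_tau if ref_tau > 1e-12 else math.nan
    return WrenchDissimilarity(delta_f, delta_tau, pct_f, pct_tau)
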