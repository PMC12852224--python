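"""Vertebral coordinate systems from the six-landmark scheme, and the
pedicle-screw mounting frames of a spinal loading device.

Landmark semantics (all in mm):

* P1 — centre of the cranial endplate
* P2 — centre of the caudal endplate
* P3 / P4 — high / low point of the right cranial pedicle
* P5 / P6 — high / low point of the left cranial pedicle

The vertebral frame sits at the midpoint of the endplate centres with Y along
the caudal-to-cranial endplate axis (cephalad), Z anterior and X left — the
Panjabi convention — built by :func:`f_coord` from the two landmark-derived
direction vectors ``a = P2→P1`` and ``b = ½(P3→P5 + P4→P6)``.  Because the
construction uses only landmark geometry it is equivariant under rigid motion
of the vertebra, which is what lets the same recipe serve preoperative and
intraoperative configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import RigidTransform, assert_rotation

__all__ = [
    "CollinearVectorsError",
    "Frame",
    "LandmarkSet",
    "PedicleEntryPair",
    "build_mount_frames",
    "build_vertebra_frame",
    "f_coord",
]

#: Minimum angle (deg) between the two construction vectors of a frame.
MIN_CONSTRUCTION_ANGLE_DEG = 1.0

LANDMARK_ROLES = ("P1", "P2", "P3", "P4", "P5", "P6")


class CollinearVectorsError(ValueError):
    """Frame construction vectors are (near-)collinear or zero."""


@dataclass(frozen=True)
class Frame:
    """An origin plus a right-handed orthonormal orientation, expressed in a
    named parent frame.  ``orientation`` columns are the frame's axes in
    parent coordinates, so ``as_transform()`` maps frame → parent."""

    origin: np.ndarray
    orientation: np.ndarray
    parent: str = "O"
    name: str = ""

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        r = assert_rotation(self.orientation, name=f"orientation of frame {self.name or '?'}")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "orientation", r)

    def as_transform(self) -> RigidTransform:
        """``T_parent_frame``: frame coordinates → parent coordinates."""
        return RigidTransform(self.orientation, self.origin)

    @property
    def e_x(self) -> np.ndarray:
        return self.orientation[:, 0]

    @property
    def e_y(self) -> np.ndarray:
        return self.orientation[:, 1]

    @property
    def e_z(self) -> np.ndarray:
        return self.orientation[:, 2]


def _unit(v: np.ndarray, label: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise CollinearVectorsError(f"construction vector {label} is zero")
    return v / n


def f_coord(
    origin: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    *,
    parent: str = "O",
    name: str = "",
) -> Frame:
    """Orthonormal frame from two direction vectors.

    ``e_Y = a/|a|``; ``e_Z`` along ``(b/|b|) × e_Y`` (normalized, since a and
    b need not be perpendicular on a skewed vertebra); ``e_X = e_Y × e_Z``.
    With landmark-semantic inputs this yields X left, Y cephalad, Z anterior.

    Raises :class:`CollinearVectorsError` when a or b is zero or they subtend
    less than 1 degree.
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    a = np.asarray(a, dtype=float).reshape(3)
    b = np.asarray(b, dtype=float).reshape(3)
    e_y = _unit(a, "a")
    b_hat = _unit(b, "b")
    e_z = np.cross(b_hat, e_y)
    sin_angle = float(np.linalg.norm(e_z))
    if sin_angle < math.sin(math.radians(MIN_CONSTRUCTION_ANGLE_DEG)):
        raise CollinearVectorsError(
            f"construction vectors a={a.tolist()} and b={b.tolist()} subtend less than "
            f"{MIN_CONSTRUCTION_ANGLE_DEG} degree"
        )
    e_z = e_z / sin_angle
    e_x = np.cross(e_y, e_z)
    return Frame(origin, np.column_stack([e_x, e_y, e_z]), parent=parent, name=name)


@dataclass(frozen=True)
class LandmarkSet:
    """The six per-vertebra anatomical points, in mm, world coordinates."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray
    p5: np.ndarray
    p6: np.ndarray

    def __post_init__(self) -> None:
        for role in LANDMARK_ROLES:
            v = np.asarray(getattr(self, role.lower()), dtype=float).reshape(3)
            object.__setattr__(self, role.lower(), v)
        if np.linalg.norm(self.p1 - self.p2) < 1e-9:
            raise ValueError("landmarks P1 and P2 coincide: endplate axis undefined")
        a = self.vector_a
        b = self.vector_b
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if nb < 1e-12:
            raise CollinearVectorsError("pedicle landmark vector b is zero")
        cosang = abs(float(a @ b)) / (na * nb)
        if cosang > math.cos(math.radians(MIN_CONSTRUCTION_ANGLE_DEG)):
            raise CollinearVectorsError("landmark vectors a and b are collinear within 1 degree")

    @property
    def vector_a(self) -> np.ndarray:
        """Caudal-to-cranial endplate axis, P2 → P1."""
        return self.p1 - self.p2

    @property
    def vector_b(self) -> np.ndarray:
        """Mean right-to-left pedicle axis, ½(P3→P5 + P4→P6)."""
        return 0.5 * ((self.p5 - self.p3) + (self.p6 - self.p4))

    @property
    def centroid_origin(self) -> np.ndarray:
        """Vertebral centre: P1 + ½ P1→P2 (endplate-centre midpoint)."""
        return self.p1 + 0.5 * (self.p2 - self.p1)

    def points(self) -> dict[str, np.ndarray]:
        return {role: getattr(self, role.lower()) for role in LANDMARK_ROLES}

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(*(transform.apply(getattr(self, r.lower())) for r in LANDMARK_ROLES))


@dataclass(frozen=True)
class PedicleEntryPair:
    """Left/right pedicle-screw entry points (mm) plus the screw offset
    height that lifts the device mounting point off the entry axis.  The
    25 mm default is the minimal offset of the pedicle screws the loading
    scenario assumes."""

    ped_right: np.ndarray
    ped_left: np.ndarray
    h_screw: float = 25.0

    def __post_init__(self) -> None:
        pr = np.asarray(self.ped_right, dtype=float).reshape(3)
        pl = np.asarray(self.ped_left, dtype=float).reshape(3)
        object.__setattr__(self, "ped_right", pr)
        object.__setattr__(self, "ped_left", pl)
        if np.linalg.norm(pr - pl) < 1e-9:
            raise ValueError("pedicle entry points coincide")
        if not self.h_screw > 0.0:
            raise ValueError("h_screw must be positive")

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.ped_right + self.ped_left)

    def transformed(self, transform: RigidTransform) -> "PedicleEntryPair":
        return replace(
            self,
            ped_right=transform.apply(self.ped_right),
            ped_left=transform.apply(self.ped_left),
        )


def build_vertebra_frame(landmarks: LandmarkSet, *, parent: str = "O", name: str = "V") -> Frame:
    """Vertebral frame: origin at the endplate-centre midpoint, axes from
    :func:`f_coord` applied to the landmark direction vectors."""
    return f_coord(
        landmarks.centroid_origin,
        landmarks.vector_a,
        landmarks.vector_b,
        parent=parent,
        name=name,
    )


def _mount_origin_world(entries: PedicleEntryPair, vertebra: Frame) -> np.ndarray:
    # Formula is stated in vertebra coordinates: midpoint of the entry pair,
    # lowered by h_screw along the vertebra's -Y.
    t = vertebra.as_transform()
    mid_local = t.inverse().apply(entries.midpoint)
    mount_local = mid_local + np.array([0.0, -entries.h_screw, 0.0])
    return t.apply(mount_local)


def build_mount_frames(
    caudal_entries: PedicleEntryPair,
    cranial_entries: PedicleEntryPair,
    caudal_frame: Frame,
    cranial_frame: Frame,
    *,
    entries_space: str = "world",
) -> tuple[Frame, Frame]:
    """Mounting frames M1 (caudal) and M2 (cranial) of a pedicle-mounted
    loading device, rigidly attached to their vertebrae.

    Origins: entry-pair midpoint offset by ``(0, -h_screw, 0)`` in the
    vertebra frame.  Axes: :func:`f_coord` with the half inter-mount vector
    ``c = ½ M1→M2`` (negated for M2, which faces M1) and the half right-to-left
    entry vector ``d`` of the respective vertebra, all evaluated once in the
    reference configuration and frozen — the device frames must stay rigid
    under subsequent motion.

    Returns frames expressed in their vertebra frames (parents "V1", "V2").
    """
    if entries_space not in ("world", "vertebra"):
        raise ValueError("entries_space must be 'world' or 'vertebra'")
    t1 = caudal_frame.as_transform()
    t2 = cranial_frame.as_transform()
    if entries_space == "vertebra":
        caudal_entries = caudal_entries.transformed(t1)
        cranial_entries = cranial_entries.transformed(t2)

    o_m1 = _mount_origin_world(caudal_entries, caudal_frame)
    o_m2 = _mount_origin_world(cranial_entries, cranial_frame)
    c = 0.5 * (o_m2 - o_m1)
    d1 = 0.5 * (caudal_entries.ped_left - caudal_entries.ped_right)
    d2 = 0.5 * (cranial_entries.ped_left - cranial_entries.ped_right)

    m1_world = f_coord(o_m1, c, d1, name="M1")
    m2_world = f_coord(o_m2, -c, d2, name="M2")

    def _attach(mount: Frame, vertebra: Frame, parent: str) -> Frame:
        tv = vertebra.as_transform().inverse()
        return Frame(
            tv.apply(mount.origin),
            tv.rotation @ mount.orientation,
            parent=parent,
            name=mount.name,
        )

    return _attach(m1_world, caudal_frame, "V1"), _attach(m2_world, cranial_frame, "V2")
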