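"""Deterministic synthetic functional spinal units.

Builds two stacked parametric vertebrae — six landmarks and a pedicle-screw
entry pair each — with configurable skew, left–right asymmetry and
intervertebral gap, plus a rigid preoperative-to-intraoperative shift of the
cranial vertebra with magnitudes of the order seen between supine and prone
imaging of scoliotic segments (a few mm, tens of degrees).  Everything is a
pure function of its parameters and a seed, so fixtures are bit-reproducible
and no external data is needed to exercise the full pipeline.

The default geometry is loosely mid-thoracic: 22 mm body height, 15 mm
pedicle lateral offset, 5 mm intervertebral gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import LandmarkSet, PedicleEntryPair
from .geometry import RigidTransform, euler_zyx_rotation
from .joint import FsuReference
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "FsuGeneratorParams",
    "ShiftGroundTruth",
    "ShiftSpec",
    "SyntheticFsu",
    "apply_synthetic_shift",
    "generate_fsu",
    "perturb_landmarks",
]


@dataclass(frozen=True)
class FsuGeneratorParams:
    """Geometry of the two stacked vertebrae (mm, degrees).

    ``asymmetry`` scales the left pedicle outward and the right inward (and
    tilts the posterior offsets likewise), mimicking the left–right shape
    imbalance of scoliotic vertebrae; skew angles rigidly tip each vertebra
    in its resting placement.
    """

    body_height_mm: float = 22.0
    endplate_span_mm: float = 32.0
    pedicle_lateral_offset_mm: float = 15.0
    pedicle_half_gap_mm: float = 2.0
    pedicle_posterior_offset_mm: float = 10.0
    intervertebral_gap_mm: float = 5.0
    caudal_skew_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cranial_skew_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    asymmetry: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "body_height_mm",
            "endplate_span_mm",
            "pedicle_lateral_offset_mm",
            "pedicle_half_gap_mm",
            "pedicle_posterior_offset_mm",
            "intervertebral_gap_mm",
        ):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive")
        for angles in (self.caudal_skew_deg, self.cranial_skew_deg):
            if any(abs(a) >= 45.0 for a in angles):
                raise ValueError("skew angles must stay below 45 degrees in magnitude")
        if not -0.9 < self.asymmetry < 0.9:
            raise ValueError("asymmetry factor must stay in (-0.9, 0.9)")


@dataclass(frozen=True)
class SyntheticFsu:
    """A generated FSU: preoperative reference plus world-space pedicle entry
    pairs for both vertebrae."""

    reference: FsuReference
    caudal_entries: PedicleEntryPair
    cranial_entries: PedicleEntryPair
    params: FsuGeneratorParams


def _local_landmarks(p: FsuGeneratorParams) -> LandmarkSet:
    h = p.body_height_mm
    lat_r = p.pedicle_lateral_offset_mm * (1.0 - p.asymmetry)
    lat_l = p.pedicle_lateral_offset_mm * (1.0 + p.asymmetry)
    post_r = p.pedicle_posterior_offset_mm * (1.0 - 0.5 * p.asymmetry)
    post_l = p.pedicle_posterior_offset_mm * (1.0 + 0.5 * p.asymmetry)
    hg = p.pedicle_half_gap_mm
    y_ped = h / 4.0  # pedicles sit toward the cranial endplate
    return LandmarkSet(
        p1=(0.0, h / 2.0, 0.0),
        p2=(0.0, -h / 2.0, 0.0),
        p3=(-lat_r, y_ped + hg, -post_r),
        p4=(-lat_r, y_ped - hg, -post_r),
        p5=(lat_l, y_ped + hg, -post_l),
        p6=(lat_l, y_ped - hg, -post_l),
    )


def _local_entries(p: FsuGeneratorParams) -> PedicleEntryPair:
    z = -(p.pedicle_posterior_offset_mm + 6.0)
    half_span = p.endplate_span_mm / 2.0
    return PedicleEntryPair(
        ped_right=(-half_span, 0.0, z),
        ped_left=(half_span, 0.0, z),
    )


def generate_fsu(params: FsuGeneratorParams = FsuGeneratorParams()) -> SyntheticFsu:
    """Two stacked vertebrae as a preoperative FSU reference.

    The caudal vertebra is centred at the world origin; the cranial one sits
    one body height plus one intervertebral gap above it.  Each vertebra's
    landmarks and entry points are rigidly posed by its skew angles about its
    own centre, so frame construction sees exactly the asymmetry the
    parameters request.  Identical parameters give bitwise-identical output.
    """
    lm_local = _local_landmarks(params)
    entries_local = _local_entries(params)

    placements = []
    centres = (
        np.zeros(3),
        np.array([0.0, params.body_height_mm + params.intervertebral_gap_mm, 0.0]),
    )
    for centre, skew_angles in zip(centres, (params.caudal_skew_deg, params.cranial_skew_deg)):
        rot = euler_zyx_rotation(*skew_angles)
        placements.append(RigidTransform(rot, centre))

    caudal_lm = lm_local.transformed(placements[0])
    cranial_lm = lm_local.transformed(placements[1])
    ref = FsuReference.from_landmarks(caudal_lm, cranial_lm, ref_tag="PO")
    return SyntheticFsu(
        reference=ref,
        caudal_entries=entries_local.transformed(placements[0]),
        cranial_entries=entries_local.transformed(placements[1]),
        params=params,
    )


@dataclass(frozen=True)
class ShiftSpec:
    """A rigid preoperative-to-intraoperative shift of the cranial vertebra:
    rotation of ``rotation_deg`` about an axis through the caudal origin,
    plus a translation of ``translation_mm``.

    ``axis_rule`` selects the rotation axis: 'random' (seeded) or one of
    'x', 'y', 'z' (world axes).  With the axis through the caudal origin the
    shift magnitudes are recovered exactly by the pose-shift dissimilarity
    metric, for any axis direction.
    """

    translation_mm: float = 3.0
    rotation_deg: float = 20.0
    axis_rule: str = "random"
    about: str = "caudal_origin"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.translation_mm < 0.0 or self.rotation_deg < 0.0:
            raise ValueError("shift magnitudes must be non-negative")
        if self.axis_rule not in ("random", "x", "y", "z"):
            raise ValueError("axis_rule must be 'random', 'x', 'y' or 'z'")
        if self.about not in ("caudal_origin", "cranial_origin"):
            raise ValueError("about must be 'caudal_origin' or 'cranial_origin'")


@dataclass(frozen=True)
class ShiftGroundTruth:
    """What was actually applied: world transform of the cranial vertebra and
    the generating axis/magnitudes."""

    world_shift: RigidTransform
    rotation_axis: np.ndarray
    rotation_deg: float
    translation: np.ndarray

    @property
    def translation_mm(self) -> float:
        return float(np.linalg.norm(self.translation))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def apply_synthetic_shift(
    ref: FsuReference,
    spec: ShiftSpec = ShiftSpec(),
) -> tuple[RigidTransform, ShiftGroundTruth]:
    """Shift the cranial vertebra and return the intraoperative relative pose
    ``_V2 T_V1`` plus the ground truth of the applied motion."""
    rng = np.random.default_rng(spec.seed)
    if spec.axis_rule == "random":
        axis = _random_unit(rng)
    else:
        axis = np.eye(3)["xyz".index(spec.axis_rule)]
    direction = _random_unit(rng)
    translation = spec.translation_mm * direction
    rot = _ScipyRotation.from_rotvec(np.radians(spec.rotation_deg) * axis).as_matrix()

    pivot = ref.caudal.origin if spec.about == "caudal_origin" else ref.cranial.origin
    world_shift = RigidTransform(rot, pivot - rot @ pivot + translation)

    t1 = ref.caudal.as_transform()
    t2_io = world_shift @ ref.cranial.as_transform()
    relative_io = t2_io.inverse() @ t1
    truth = ShiftGroundTruth(world_shift, axis, spec.rotation_deg, translation)
    return relative_io, truth


def perturb_landmarks(lm: LandmarkSet, sd_mm: float, seed: int = 0) -> LandmarkSet:
    """Isotropic Gaussian jitter on every landmark — a stand-in for manual
    annotation error.  ``sd_mm = 0`` returns the input unchanged."""
    if sd_mm < 0.0:
        raise ValueError("sd_mm must be non-negative")
    if sd_mm == 0.0:
        return lm
    rng = np.random.default_rng(seed)
    pts = {role.lower(): point + rng.normal(scale=sd_mm, size=3) for role, point in lm.points().items()}
    return LandmarkSet(**pts)
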