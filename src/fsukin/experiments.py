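"""The dissimilarity study as a reproducible pipeline.

For a functional spinal unit whose rest pose shifted between the preoperative
and the intraoperative configuration, the same commanded single-axis motion
generally lands the cranial vertebra in different places depending on whether
the joint frame was referenced preoperatively (PO) or intraoperatively (IO),
and on the single-/double-parent orientation policy.  This module sweeps
single-axis bends and translations under both references, compares the
outcome poses, and propagates single-axis loads through the adjoint to
compare the wrench a pedicle-mounted device would have to deliver.

Outcome poses are compared in the caudal-vertebra frame (positions of the
cranial frame origin); the percentage column is taken against the
IO-referenced outcome's relative-position norm.  Wrench rows pair each
translation axis with a force and each bend axis with a torque along the same
axis, the load sign following the displacement sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import Frame
from .geometry import RigidTransform, pose_dissimilarity
from .joint import (
    FsuReference,
    JointDefinition,
    ParentMode,
    apply_single_axis_motion,
    build_joint,
    shift_reference,
)
from .wrench import Wrench, required_wrench, wrench_dissimilarity

__all__ = [
    "BEND_AXES",
    "RESULT_COLUMNS",
    "TRANSLATION_AXES",
    "SweepSpec",
    "run_motion_dissimilarity",
    "run_wrench_dissimilarity",
    "summarize",
]

TRANSLATION_AXES = ("x", "y", "z")
BEND_AXES = ("alpha", "beta", "gamma")

#: Physiological reading of each joint axis.
AXIS_DIRECTIONS = {
    "x": "translation M/L",
    "y": "compression/decompression",
    "z": "translation AP/PA",
    "alpha": "flexion/extension",
    "beta": "axial rotation R/L",
    "gamma": "lateral bending R/L",
}

RESULT_COLUMNS = [
    "fsu",
    "condition",
    "mode",
    "axis",
    "magnitude",
    "load",
    "delta_r_mm",
    "delta_R_deg",
    "pct_r",
    "delta_F_N",
    "delta_tau_Nm",
    "pct_F",
    "pct_tau",
]


@dataclass(frozen=True)
class SweepSpec:
    """Magnitude grids of the virtual-motion and loading sweeps.  Values are
    expanded to both signs: bending angles in degrees, translations in mm,
    torques in Nm, forces in N."""

    bend_angles_deg: tuple[float, ...] = (5.0, 10.0, 15.0)
    translations_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    torques_Nm: tuple[float, ...] = (5.0, 7.5, 10.0)
    forces_N: tuple[float, ...] = (5.0, 10.0, 15.0)

    def __post_init__(self) -> None:
        for name in ("bend_angles_deg", "translations_mm", "torques_Nm", "forces_N"):
            values = getattr(self, name)
            if len(values) == 0 or not all(math.isfinite(v) for v in values):
                raise ValueError(f"{name} must be a nonempty tuple of finite values")

    @staticmethod
    def signed(values: tuple[float, ...]) -> list[float]:
        out: list[float] = []
        for v in values:
            out.extend([-v, v])
        return sorted(set(out))


def _joints(
    po_ref: FsuReference,
    io_relative: RigidTransform,
    mode: ParentMode,
    origin_convention: str,
) -> tuple[JointDefinition, JointDefinition, FsuReference]:
    io_ref = shift_reference(po_ref, io_relative)
    jd_po = build_joint(po_ref, mode, origin_convention=origin_convention)
    jd_io = build_joint(io_ref, mode, origin_convention=origin_convention)
    return jd_po, jd_io, io_ref


def _compare_outcomes(po_out: RigidTransform, io_out: RigidTransform):
    # Positions of the cranial origin in the caudal frame: invert _V2 T_V1.
    po_caudal = po_out.inverse()
    io_caudal = io_out.inverse()
    return pose_dissimilarity(po_caudal, io_caudal, denominator=io_caudal)


def run_motion_dissimilarity(
    po_ref: FsuReference,
    io_relative: RigidTransform,
    mode: ParentMode = ParentMode(),
    sweep: SweepSpec = SweepSpec(),
    *,
    convention: str = "increment",
    origin_convention: str = "bounding",
    fsu: str = "FSU",
) -> pd.DataFrame:
    """PO-vs-IO pose dissimilarity of every single-axis motion in the sweep.

    Both joints command the motion from the same intraoperative equilibrium
    pose; each row reports where the cranial vertebra ends up under the two
    references.
    """
    jd_po, jd_io, _ = _joints(po_ref, io_relative, mode, origin_convention)
    rows = []
    axis_grid = [(a, SweepSpec.signed(sweep.translations_mm)) for a in TRANSLATION_AXES]
    axis_grid += [(a, SweepSpec.signed(sweep.bend_angles_deg)) for a in BEND_AXES]
    for axis, magnitudes in axis_grid:
        for magnitude in magnitudes:
            po_out = apply_single_axis_motion(jd_po, io_relative, axis, magnitude, convention=convention)
            io_out = apply_single_axis_motion(jd_io, io_relative, axis, magnitude, convention=convention)
            d = _compare_outcomes(po_out, io_out)
            rows.append({
                "fsu": fsu,
                "condition": "PO_vs_IO",
                "mode": mode.kind,
                "axis": axis,
                "magnitude": magnitude,
                "load": math.nan,
                "delta_r_mm": d.delta_r_mm,
                "delta_R_deg": d.delta_R_deg,
                "pct_r": d.percent_r,
                "delta_F_N": math.nan,
                "delta_tau_Nm": math.nan,
                "pct_F": math.nan,
                "pct_tau": math.nan,
            })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _single_axis_wrench(axis: str, load: float) -> Wrench:
    force = np.zeros(3)
    torque = np.zeros(3)
    if axis in TRANSLATION_AXES:
        force[TRANSLATION_AXES.index(axis)] = load
    else:
        torque[BEND_AXES.index(axis)] = load
    return Wrench(force, torque, frame="A")


def run_wrench_dissimilarity(
    po_ref: FsuReference,
    io_relative: RigidTransform,
    mode: ParentMode,
    sweep: SweepSpec,
    mounts: tuple[Frame, Frame],
    *,
    convention: str = "increment",
    adjoint_convention: str = "literal",
    origin_convention: str = "bounding",
    fsu: str = "FSU",
) -> pd.DataFrame:
    """PO-vs-IO dissimilarity of the wrench required at mounting frame M2.

    For every displaced pose of the motion sweep, a single-axis load is
    applied at the respective joint frame along the displacement axis (forces
    with translations, torques with bends) and mapped to M2 through the
    adjoint at the displaced configuration.
    """
    jd_po, jd_io, _ = _joints(po_ref, io_relative, mode, origin_convention)
    rows = []
    axis_grid = [
        (a, SweepSpec.signed(sweep.translations_mm), sweep.forces_N) for a in TRANSLATION_AXES
    ]
    axis_grid += [
        (a, SweepSpec.signed(sweep.bend_angles_deg), sweep.torques_Nm) for a in BEND_AXES
    ]
    for axis, magnitudes, loads in axis_grid:
        for magnitude in magnitudes:
            po_out = apply_single_axis_motion(jd_po, io_relative, axis, magnitude, convention=convention)
            io_out = apply_single_axis_motion(jd_io, io_relative, axis, magnitude, convention=convention)
            for load_level in loads:
                load = math.copysign(load_level, magnitude)
                w_a = _single_axis_wrench(axis, load)
                w_po = required_wrench(jd_po, po_out, mounts, w_a, convention=adjoint_convention)
                w_io = required_wrench(jd_io, io_out, mounts, w_a, convention=adjoint_convention)
                wd = wrench_dissimilarity(w_po, w_io)
                rows.append({
                    "fsu": fsu,
                    "condition": "PO_vs_IO",
                    "mode": mode.kind,
                    "axis": axis,
                    "magnitude": magnitude,
                    "load": load,
                    "delta_r_mm": math.nan,
                    "delta_R_deg": math.nan,
                    "pct_r": math.nan,
                    "delta_F_N": wd.delta_F_N,
                    "delta_tau_Nm": wd.delta_tau_Nm,
                    "pct_F": wd.percent_F,
                    "pct_tau": wd.percent_tau,
                })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


_SUMMARY_METRICS = ("delta_r_mm", "delta_R_deg", "pct_r", "delta_F_N", "delta_tau_Nm", "pct_F", "pct_tau")


def summarize(rows: pd.DataFrame) -> dict[str, dict]:
    """Maxima of every metric with their provenance (fsu, axis, magnitude).

    Metrics that are NaN throughout (e.g. wrench columns of a motion sweep)
    are omitted.  Raises on an empty row set.
    """
    if len(rows) == 0:
        raise ValueError("cannot summarize an empty row set")
    out: dict[str, dict] = {}
    for metric in _SUMMARY_METRICS:
        col = rows[metric]
        if col.isna().all():
            continue
        idx = col.idxmax()
        row = rows.loc[idx]
        out[metric] = {
            "max": float(row[metric]),
            "fsu": row["fsu"],
            "mode": row["mode"],
            "axis": row["axis"],
            "magnitude": float(row["magnitude"]),
            "load": None if math.isnan(row["load"]) else float(row["load"]),
        }
    return out
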