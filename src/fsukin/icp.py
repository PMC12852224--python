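"""Adapter around a standard iterative-closest-point routine for rigid
vertebra-to-vertebra mesh registration.

The core fit is delegated to :func:`trimesh.registration.icp` (rigid: no
scaling, no reflection).  Settings map as follows: ``inlier_ratio`` is the
fraction of the surface point samples actually used per repeat (each repeat
re-draws its sample, which is also what makes repeats differ), the lower end
of ``tolerance_interval_mm`` is the convergence threshold, and
``max_iterations`` caps the iterations.  Run-to-run spread across repeats is
reported rather than hidden: each repeat's transform is compared against the
first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import RigidTransform, pose_dissimilarity
from .io import IcpSettings

__all__ = ["IcpResult", "fit_icp"]


@dataclass(frozen=True)
class IcpResult:
    """Per-repeat transforms (moving → fixed), costs, and the spread of each
    repeat against the first."""

    transforms: list[RigidTransform]
    costs: list[float]
    spread: pd.DataFrame


def _load_mesh(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh")
    if mesh.vertices.shape[0] < 4 or mesh.faces.shape[0] < 1:
        raise ValueError(f"degenerate mesh: {path}")
    return mesh


def fit_icp(
    fixed_mesh: str | Path,
    moving_mesh: str | Path,
    settings: IcpSettings = IcpSettings(),
) -> IcpResult:
    """Fit the moving mesh onto the fixed mesh, one rigid transform per
    repeat."""
    fixed = _load_mesh(fixed_mesh)
    moving = _load_mesh(moving_mesh)
    n_used = max(4, int(settings.samples * settings.inlier_ratio))

    # Register against a dense point sampling of the fixed surface
    # (nearest-neighbour correspondences via a KD-tree).
    fixed_points, _ = trimesh.sample.sample_surface(
        fixed, 4 * settings.samples, seed=settings.seed
    )

    transforms: list[RigidTransform] = []
    costs: list[float] = []
    for repeat in range(settings.repeats):
        points, _ = trimesh.sample.sample_surface(
            moving, settings.samples, seed=settings.seed + 1 + repeat
        )
        points = points[:n_used]
        matrix, _, cost = trimesh.registration.icp(
            points,
            fixed_points,
            threshold=settings.tolerance_interval_mm[0],
            max_iterations=settings.max_iterations,
            scale=False,
            reflection=False,
        )
        transforms.append(RigidTransform.from_matrix(np.asarray(matrix)))
        costs.append(float(cost))

    rows = []
    for i, t in enumerate(transforms):
        d = pose_dissimilarity(t, transforms[0], denominator=transforms[0])
        rows.append({
            "repeat": i + 1,
            "delta_r_mm": d.delta_r_mm,
            "delta_R_deg": d.delta_R_deg,
            "cost": costs[i],
        })
    return IcpResult(transforms, costs, pd.DataFrame(rows))
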