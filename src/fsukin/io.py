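"""File I/O: landmark files (Slicer FCSV, markups JSON, plain CSV), 4x4
transform files, result CSVs and the declarative experiment configuration.

Coordinates are normalized at the boundary to a single internal space, LPS
(x left? no — x toward the patient's left is the anatomical X of the frames;
LPS here names the CT-native axis convention: first axis Left, second
Posterior, third Superior).  Slicer fiducials may declare RAS, in which case
the first two coordinates are sign-flipped on read.  Lengths are mm, angles
degrees, forces N, torques Nm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frames import LANDMARK_ROLES, LandmarkSet, PedicleEntryPair
from .geometry import RigidTransform

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "IcpSettings",
    "INTERNAL_SPACE",
    "load_config",
    "read_landmarks",
    "read_pedicle_entries",
    "read_points",
    "read_transform",
    "write_landmarks",
    "write_pedicle_entries",
    "write_points",
    "write_results_csv",
    "write_transform",
]

INTERNAL_SPACE = "LPS"
ENTRY_ROLES = ("PedR", "PedL")

_DIALECTS = ("fcsv", "markups_json", "csv")


class ConfigError(ValueError):
    """Configuration validation failed; the message lists every problem."""


def _dialect_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in _DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
        return dialect
    suffix = path.suffix.lower()
    if suffix == ".fcsv":
        return "fcsv"
    if suffix == ".json":
        return "markups_json"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer landmark dialect from suffix of {path.name!r}")


def _normalize_space(points: dict[str, np.ndarray], space: str) -> dict[str, np.ndarray]:
    space = space.upper()
    if space == INTERNAL_SPACE:
        return points
    if space == "RAS":
        flip = np.array([-1.0, -1.0, 1.0])
        return {label: p * flip for label, p in points.items()}
    raise ValueError(f"unknown coordinate space {space!r}; expected LPS or RAS")


def read_points(path: str | Path, dialect: str | None = None) -> dict[str, np.ndarray]:
    """Labelled 3D points from a landmark file, normalized to the internal
    coordinate space.  Duplicate labels are an error."""
    path = Path(path)
    dialect = _dialect_for(path, dialect)
    points: list[tuple[str, np.ndarray]] = []
    space = INTERNAL_SPACE

    if dialect == "fcsv":
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line:
                    token = line.split("=")[-1].strip()
                    space = {"0": "RAS", "1": "LPS"}.get(token, token)
                continue
            fields = line.split(",")
            if len(fields) < 12:
                raise ValueError(f"malformed FCSV row in {path.name}: {line!r}")
            label = fields[11].strip()
            points.append((label, np.array([float(v) for v in fields[1:4]])))
    elif dialect == "markups_json":
        doc = json.loads(path.read_text())
        try:
            markup = doc["markups"][0]
        except (KeyError, IndexError) as exc:
            raise ValueError(f"{path.name} is not a markups JSON file") from exc
        space = markup.get("coordinateSystem", INTERNAL_SPACE)
        for cp in markup.get("controlPoints", []):
            points.append((cp["label"], np.asarray(cp["position"], dtype=float)))
    else:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
        required = {"label", "x", "y", "z"}
        if not required.issubset(frame.columns):
            raise ValueError(f"{path.name} must have columns {sorted(required)}")
        if "space" in frame.columns and len(frame):
            declared = set(frame["space"].astype(str).str.upper())
            if len(declared) > 1:
                raise ValueError(f"{path.name} declares multiple coordinate spaces")
            space = declared.pop()
        for _, row in frame.iterrows():
            points.append((str(row["label"]), np.array([row["x"], row["y"], row["z"]], dtype=float)))

    labels = [label for label, _ in points]
    duplicates = {label for label in labels if labels.count(label) > 1}
    if duplicates:
        raise ValueError(f"duplicate point labels in {path.name}: {sorted(duplicates)}")
    return _normalize_space(dict(points), space)


def _pick_roles(points: dict[str, np.ndarray], roles: tuple[str, ...], path: Path) -> list[np.ndarray]:
    lookup = {label.upper(): p for label, p in points.items()}
    missing = [role for role in roles if role.upper() not in lookup]
    if missing:
        raise ValueError(f"{path.name} is missing landmark role(s): {missing}")
    return [lookup[role.upper()] for role in roles]


def read_landmarks(path: str | Path, dialect: str | None = None) -> LandmarkSet:
    """A six-role landmark set (labels P1..P6, case-insensitive) in the
    internal coordinate space."""
    path = Path(path)
    pts = _pick_roles(read_points(path, dialect), LANDMARK_ROLES, path)
    return LandmarkSet(*pts)


def read_pedicle_entries(
    path: str | Path,
    dialect: str | None = None,
    *,
    h_screw: float = 25.0,
) -> PedicleEntryPair:
    """Pedicle entry pair (labels PedR/PedL) with the configured screw
    height."""
    path = Path(path)
    right, left = _pick_roles(read_points(path, dialect), ENTRY_ROLES, path)
    return PedicleEntryPair(right, left, h_screw=h_screw)


def write_points(
    path: str | Path,
    points: dict[str, np.ndarray],
    dialect: str | None = None,
    *,
    space: str = INTERNAL_SPACE,
) -> None:
    """Write labelled points in the requested dialect, declaring ``space``.

    Points are given in the internal space and converted on write when a
    different space is declared, so write→read round trips are lossless.
    """
    path = Path(path)
    dialect = _dialect_for(path, dialect)
    out = _normalize_space(points, space)  # LPS↔RAS flip is an involution

    if dialect == "fcsv":
        lines = [
            "# Markups fiducial file version = 4.11",
            f"# CoordinateSystem = {space.upper()}",
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
        ]
        for i, (label, p) in enumerate(out.items()):
            lines.append(
                f"vtkMRMLMarkupsFiducialNode_{i},{float(p[0])!r},{float(p[1])!r},{float(p[2])!r},"
                f"0,0,0,1,1,1,0,{label},,"
            )
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "markups_json":
        doc = {
            "markups": [
                {
                    "type": "Fiducial",
                    "coordinateSystem": space.upper(),
                    "controlPoints": [
                        {"label": label, "position": list(map(float, p))}
                        for label, p in out.items()
                    ],
                }
            ]
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        rows = [
            {"label": label, "x": p[0], "y": p[1], "z": p[2], "space": space.upper()}
            for label, p in out.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_landmarks(path: str | Path, lm: LandmarkSet, dialect: str | None = None, *, space: str = INTERNAL_SPACE) -> None:
    write_points(path, {role: getattr(lm, role.lower()) for role in LANDMARK_ROLES}, dialect, space=space)


def write_pedicle_entries(path: str | Path, entries: PedicleEntryPair, dialect: str | None = None, *, space: str = INTERNAL_SPACE) -> None:
    write_points(path, {"PedR": entries.ped_right, "PedL": entries.ped_left}, dialect, space=space)


def read_transform(path: str | Path) -> RigidTransform:
    """A 4x4 homogeneous rigid transform from JSON (``{"matrix": ...}``) or
    whitespace-separated text; translation in mm.

    A rotation block with orthonormality drift above 1e-6 is re-orthonormalized
    with a warning; a block that is not rigid within 1e-3 (or has a negative
    determinant) is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        matrix = np.asarray(doc["matrix"], dtype=float)
    else:
        matrix = np.loadtxt(path, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError(f"{path.name}: expected a 4x4 matrix, got shape {matrix.shape}")
    if not np.allclose(matrix[3], [0, 0, 0, 1], atol=1e-9):
        raise ValueError(f"{path.name}: bottom row must be (0, 0, 0, 1)")
    r = matrix[:3, :3]
    det = float(np.linalg.det(r))
    drift = float(np.abs(r.T @ r - np.eye(3)).max())
    if det <= 0.0 or drift > 1e-3:
        raise ValueError(
            f"{path.name}: matrix is not a rigid transform (det={det:.6g}, drift={drift:.3g})"
        )
    if drift > 1e-6:
        warnings.warn(
            f"{path.name}: rotation drift {drift:.3g} exceeds 1e-6; re-orthonormalizing",
            stacklevel=2,
        )
        u, _, vt = np.linalg.svd(r)
        r = u @ vt
    return RigidTransform(r, matrix[:3, 3])


def write_transform(path: str | Path, transform: RigidTransform) -> None:
    path = Path(path)
    matrix = transform.as_matrix()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"matrix": matrix.tolist()}, indent=2) + "\n")
    else:
        np.savetxt(path, matrix, fmt="%.17g")


def write_results_csv(rows: pd.DataFrame, path: str | Path) -> None:
    """Result rows with the fixed dissimilarity schema; undefined percentages
    serialize as ``NaN``.  Formatting is fixed so identical runs produce
    byte-identical files."""
    rows.to_csv(path, index=False, na_rep="NaN", float_format="%.10g")


@dataclass(frozen=True)
class IcpSettings:
    """Parameters of the mesh-registration adapter (see :mod:`fsukin.icp`)."""

    inlier_ratio: float = 0.8
    max_iterations: int = 500
    tolerance_interval_mm: tuple[float, float] = (0.01, 0.1)
    repeats: int = 3
    samples: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.inlier_ratio <= 1.0:
            raise ValueError("inlier_ratio must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


@dataclass
class ExperimentConfig:
    """Declarative description of one dissimilarity run."""

    caudal_landmarks: str = ""
    cranial_landmarks: str = ""
    caudal_entries: str = ""
    cranial_entries: str = ""
    io_transform: str = ""
    parent_modes: list[str] = field(default_factory=lambda: ["single", "double"])
    motion_convention: str = "increment"
    adjoint_convention: str = "literal"
    origin_convention: str = "bounding"
    bend_angles_deg: list[float] = field(default_factory=lambda: [5.0, 10.0, 15.0])
    translations_mm: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0])
    torques_Nm: list[float] = field(default_factory=lambda: [5.0, 7.5, 10.0])
    forces_N: list[float] = field(default_factory=lambda: [5.0, 10.0, 15.0])
    h_screw: float = 25.0
    seed: int = 0
    output_dir: str = "results"
    fsu: str = "FSU"

    def validate(self, *, require_entries: bool = False) -> None:
        problems: list[str] = []
        for label, value in (
            ("caudal_landmarks", self.caudal_landmarks),
            ("cranial_landmarks", self.cranial_landmarks),
            ("io_transform", self.io_transform),
        ):
            if not value:
                problems.append(f"{label} is not set")
            elif not Path(value).exists():
                problems.append(f"{label} file does not exist: {value}")
        if require_entries:
            for label, value in (
                ("caudal_entries", self.caudal_entries),
                ("cranial_entries", self.cranial_entries),
            ):
                if not value:
                    problems.append(f"{label} is not set")
                elif not Path(value).exists():
                    problems.append(f"{label} file does not exist: {value}")
        if not self.h_screw > 0.0:
            problems.append("h_screw must be positive")
        for mode in self.parent_modes:
            if mode not in ("single", "double"):
                problems.append(f"unknown parent mode {mode!r}")
        if self.motion_convention not in ("increment", "parameter"):
            problems.append(f"unknown motion convention {self.motion_convention!r}")
        if self.adjoint_convention not in ("literal", "power"):
            problems.append(f"unknown adjoint convention {self.adjoint_convention!r}")
        if self.origin_convention not in ("bounding", "outer"):
            problems.append(f"unknown origin convention {self.origin_convention!r}")
        if problems:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))


def load_config(path: str | Path) -> ExperimentConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return ExperimentConfig(**doc)
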