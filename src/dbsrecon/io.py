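"""Readers and writers for the tabular (CSV), mesh (OBJ) and config formats.

All tabular interchange is plain CSV (period decimal separator, header row
mandatory, ``\\n`` line endings) so fixtures stay human-diffable; meshes are
Wavefront OBJ because an exact text round-trip is testable.  Analytic
structures may alternatively be given as JSON
``{"type": "sphere"|"ellipsoid", "center": [...], "radii": [...],
"label": ..., "side": ...}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import trimesh
import yaml

from .acpc import Hemisphere
from .atlas import AnalyticEllipsoid, StructureMesh
from .simulate import SimulationConfig

__all__ = [
    "COORD_COLUMNS",
    "DIST_COLUMNS",
    "CoordinateParseError",
    "POINT_ROLES",
    "load_config",
    "read_coordinate_csv",
    "read_distances_csv",
    "read_mesh_obj",
    "read_structure_json",
    "write_coordinate_csv",
    "write_distances_csv",
    "write_mesh_obj",
]

COORD_COLUMNS = [
    "patient_id", "side", "method", "point_role", "x_mm", "y_mm", "z_mm",
]
DIST_COLUMNS = ["patient_id", "side", "euclid_a_mm", "euclid_b_mm", "mer_mm"]

POINT_ROLES = frozenset(
    {"ventral_contact", "cranial_point", "planned_target"}
    | {f"contact_{k}" for k in range(8)}
)
SIDES = frozenset(h.value for h in Hemisphere)


class CoordinateParseError(ValueError):
    """A CSV row or header violates the coordinate-table schema."""


def read_coordinate_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a coordinate table; row order is preserved.

    Raises :class:`CoordinateParseError` naming the offending column and
    1-based data row on the first violation.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COORD_COLUMNS if c not in df.columns]
    if missing:
        raise CoordinateParseError(f"missing column(s): {', '.join(missing)}")
    df = df.loc[:, COORD_COLUMNS]
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        if row.side not in SIDES:
            raise CoordinateParseError(
                f"row {row_no}: unknown side {row.side!r}"
            )
        if row.point_role not in POINT_ROLES:
            raise CoordinateParseError(
                f"row {row_no}: unknown point_role {row.point_role!r}"
            )
        for col in ("x_mm", "y_mm", "z_mm"):
            v = getattr(row, col)
            try:
                v = float(v)
            except (TypeError, ValueError):
                v = np.nan
            if not np.isfinite(v):
                raise CoordinateParseError(
                    f"row {row_no}: non-numeric value in column {col}"
                )
    df[["x_mm", "y_mm", "z_mm"]] = df[["x_mm", "y_mm", "z_mm"]].astype(float)
    return df


def write_coordinate_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a coordinate table with fixed column order and ``\\n`` endings."""
    df.loc[:, COORD_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_distances_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in DIST_COLUMNS if c not in df.columns]
    if missing:
        raise CoordinateParseError(f"missing column(s): {', '.join(missing)}")
    df = df.loc[:, DIST_COLUMNS]
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        if row.side not in SIDES:
            raise CoordinateParseError(f"row {row_no}: unknown side {row.side!r}")
        for col in ("euclid_a_mm", "euclid_b_mm", "mer_mm"):
            v = getattr(row, col)
            if not np.isfinite(float(v)):
                raise CoordinateParseError(
                    f"row {row_no}: non-numeric value in column {col}"
                )
    return df


def write_distances_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.loc[:, DIST_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_mesh_obj(
    path: Union[str, Path], label: str, side: Hemisphere
) -> StructureMesh:
    """Load a Wavefront OBJ (v/f records, 1-based indices) as a structure.

    The mesh must satisfy the closed-surface invariants; an open mesh raises
    :class:`~dbsrecon.atlas.MeshValidationError` reporting the number of
    boundary edges.
    """
    m = trimesh.load(str(path), file_type="obj", process=False, force="mesh")
    return StructureMesh(mesh=m, label=label, side=side)


def write_mesh_obj(sm: StructureMesh, path: Union[str, Path]) -> None:
    Path(path).write_text(
        trimesh.exchange.obj.export_obj(
            sm.mesh, include_normals=False, include_texture=False, digits=12
        )
    )


def read_structure_json(path: Union[str, Path]) -> AnalyticEllipsoid:
    """Read an analytic sphere/ellipsoid structure description."""
    from .acpc import Point3

    d = json.loads(Path(path).read_text())
    shape_type = d.get("type")
    if shape_type not in ("sphere", "ellipsoid"):
        raise ValueError(f"unknown analytic shape type {shape_type!r}")
    if shape_type == "sphere":
        r = float(d["radius"]) if "radius" in d else float(d["radii"])
        radii = (r, r, r)
    else:
        radii = tuple(float(v) for v in d["radii"])
        if len(radii) != 3:
            raise ValueError("ellipsoid radii must have 3 components")
    return AnalyticEllipsoid(
        center=Point3.from_array(np.asarray(d["center"], float)),
        radii=radii,
        label=str(d["label"]),
        side=Hemisphere(str(d["side"])),
    )


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load a simulation config from YAML or JSON (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return SimulationConfig.from_dict(data)
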