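"""End-to-end pipeline: simulate -> contacts -> relative position -> compare.

Each stage consumes and produces the documented CSV/OBJ interfaces, so the
stages are usable standalone (see :mod:`dbsrecon.cli`) and the whole chain
is reproducible from a :class:`RunManifest`: re-running with the manifest's
config and seed yields byte-identical CSV outputs.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .acpc import Hemisphere, Point3
from .atlas import StructureMesh, relative_position_record
from .comparison import (
    ComparisonResult,
    DistanceValidationRecord,
    PairedCoordinateTable,
    consistency_rate,
    distance_validation,
    mean_discrepancy,
    paired_axis_test,
    subregion_rate,
)
from .atlas import contact_subregion
from .electrode import (
    BUILTIN_SPECS,
    ContactSet,
    fit_trajectory,
    interpolate_contacts,
    tip_position,
)
from .io import (
    COORD_COLUMNS,
    write_coordinate_csv,
    write_distances_csv,
    write_mesh_obj,
)
from .simulate import (
    SimulationConfig,
    generate_anatomy,
    generate_implants,
    generate_measurements,
)

__all__ = [
    "RunManifest",
    "contacts_from_landmarks",
    "distances_from_contacts",
    "relpos_from_contacts",
    "results_to_frame",
    "run_pipeline",
    "simulate_to_dir",
    "table_from_contacts",
    "write_report",
]

logger = logging.getLogger(__name__)

try:
    _VERSION = _pkg_version("dbsrecon")
except PackageNotFoundError:  # running from a source tree
    _VERSION = "0+unknown"

_ANATOMY_FILES = {
    ("STN", Hemisphere.RIGHT): "stn_right.obj",
    ("STN", Hemisphere.LEFT): "stn_left.obj",
    ("RN", Hemisphere.RIGHT): "rn_right.obj",
    ("RN", Hemisphere.LEFT): "rn_left.obj",
    ("STN_dorsolateral", Hemisphere.RIGHT): "stn_dorsolateral_right.obj",
    ("STN_dorsolateral", Hemisphere.LEFT): "stn_dorsolateral_left.obj",
}


@dataclass
class RunManifest:
    """Snapshot sufficient to reproduce a run byte-for-byte (CSV outputs)."""

    config: dict
    seed: int
    inputs: dict
    outputs: dict
    tool_version: str = _VERSION
    timestamp: str = ""

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path | str) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def simulate_to_dir(
    config: SimulationConfig, outdir: Path | str
) -> dict[str, str]:
    """Generate anatomy, landmarks and MER depths into an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    anatomy_dir = outdir / "anatomy"
    anatomy_dir.mkdir(exist_ok=True)
    anatomy = generate_anatomy(config)
    for key, fname in _ANATOMY_FILES.items():
        write_mesh_obj(anatomy[key], anatomy_dir / fname)
    implants = generate_implants(config, anatomy)
    meas = generate_measurements(config, implants)
    landmarks_path = outdir / "landmarks.csv"
    write_coordinate_csv(meas.landmarks, landmarks_path)
    mer = pd.DataFrame(
        {
            "patient_id": [i.patient_id for i in implants],
            "side": [i.side.value for i in implants],
            "mer_mm": [i.mer_distance for i in implants],
        }
    )
    mer_path = outdir / "mer.csv"
    mer.to_csv(mer_path, index=False, lineterminator="\n")
    return {
        "anatomy_dir": str(anatomy_dir),
        "landmarks": str(landmarks_path),
        "mer": str(mer_path),
    }


def contacts_from_landmarks(
    landmarks: pd.DataFrame, electrode_model: str = "Medtronic 3389"
) -> pd.DataFrame:
    """Interpolate all contact centres from per-method landmark pairs.

    Returns rows in the coordinate-CSV schema with ``point_role``
    ``contact_0`` ... ``contact_{n-1}`` (ventral-most first).
    """
    spec = BUILTIN_SPECS[electrode_model]
    rows = []
    grouped = landmarks[landmarks["point_role"].isin(["ventral_contact", "cranial_point"])]
    for (pid, side, method), grp in grouped.groupby(
        ["patient_id", "side", "method"], sort=True
    ):
        roles = grp.set_index("point_role")
        if not {"ventral_contact", "cranial_point"} <= set(roles.index):
            raise ValueError(
                f"electrode {pid}/{side}/{method}: both landmark roles required"
            )
        v = Point3(*roles.loc["ventral_contact", ["x_mm", "y_mm", "z_mm"]].astype(float))
        c = Point3(*roles.loc["cranial_point", ["x_mm", "y_mm", "z_mm"]].astype(float))
        cs = interpolate_contacts(fit_trajectory(v, c), spec, side=Hemisphere(side))
        for k, pt in enumerate(cs.contacts):
            rows.append(
                {
                    "patient_id": pid, "side": side, "method": method,
                    "point_role": f"contact_{k}",
                    "x_mm": pt.x, "y_mm": pt.y, "z_mm": pt.z,
                }
            )
    return pd.DataFrame(rows, columns=COORD_COLUMNS)


def table_from_contacts(contacts: pd.DataFrame) -> PairedCoordinateTable:
    """Average the contact centres per electrode and method."""
    rows = []
    for (pid, side, method), grp in contacts.groupby(
        ["patient_id", "side", "method"], sort=True
    ):
        xyz = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(float).mean(axis=0)
        rows.append(
            {
                "patient_id": pid, "side": side, "method": method,
                "x": xyz[0], "y": xyz[1], "z": xyz[2],
            }
        )
    return PairedCoordinateTable(pd.DataFrame(rows))


def _contact_set(grp: pd.DataFrame, side: Hemisphere,
                 electrode_model: str) -> ContactSet:
    spec = BUILTIN_SPECS[electrode_model]
    grp = grp.sort_values("point_role")
    pts = tuple(
        Point3(r.x_mm, r.y_mm, r.z_mm) for r in grp.itertuples(index=False)
    )
    return ContactSet(contacts=pts, side=side, spec=spec)


def relpos_from_contacts(
    contacts: pd.DataFrame,
    anatomy: dict[tuple[str, Hemisphere], StructureMesh],
    slice_step: float = 0.1,
) -> pd.DataFrame:
    """Run the RN-level relative-position construction for every electrode."""
    rows = []
    for (pid, side, method), grp in contacts.groupby(
        ["patient_id", "side", "method"], sort=True
    ):
        h = Hemisphere(side)
        cs = _contact_set(grp, h, "Medtronic 3389")
        rec = relative_position_record(
            anatomy[("STN", h)], anatomy[("RN", h)], cs, slice_step=slice_step
        )
        rows.append(
            {
                "patient_id": pid, "side": side, "method": method,
                "rn_level_z": rec.rn_level_z,
                "relative_distance_mm": (
                    np.nan if rec.relative_distance is None else rec.relative_distance
                ),
                "category": rec.category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "side", "method",
            "rn_level_z", "relative_distance_mm", "category",
        ],
    )


def distances_from_contacts(
    contacts: pd.DataFrame,
    landmarks: pd.DataFrame,
    mer: pd.DataFrame,
    method_a: str = "leaddbs",
    method_b: str = "surgiplan",
    electrode_model: str = "Medtronic 3389",
) -> pd.DataFrame:
    """Tip-to-planned-target Euclidean distances per method, plus MER depth."""
    spec = BUILTIN_SPECS[electrode_model]
    targets = landmarks[landmarks["point_role"] == "planned_target"].set_index(
        ["patient_id", "side"]
    )
    mer_idx = mer.set_index(["patient_id", "side"])["mer_mm"]
    rows = []
    for (pid, side), grp in contacts.groupby(["patient_id", "side"], sort=True):
        target = Point3(
            *targets.loc[(pid, side), ["x_mm", "y_mm", "z_mm"]].astype(float)
        )
        tips = {}
        for method, mgrp in grp.groupby("method"):
            cs = _contact_set(mgrp, Hemisphere(side), electrode_model)
            pts = cs.as_array()
            d = pts[-1] - pts[0]
            d = d / np.linalg.norm(d)
            traj = fit_trajectory(cs.contacts[0], Point3.from_array(pts[0] + 10 * d))
            tips[method] = tip_position(traj, spec)
        rows.append(
            {
                "patient_id": pid,
                "side": side,
                "euclid_a_mm": tips[method_a].distance_to(target),
                "euclid_b_mm": tips[method_b].distance_to(target),
                "mer_mm": float(mer_idx.loc[(pid, side)]),
            }
        )
    return pd.DataFrame(rows, columns=[
        "patient_id", "side", "euclid_a_mm", "euclid_b_mm", "mer_mm",
    ])


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _axis_scope_sd(table: PairedCoordinateTable, axis: str, scope: str,
                   method: str) -> float:
    return float(table.axis_values(axis, scope)[method].std(ddof=1))


def write_report(
    table: PairedCoordinateTable,
    results: list[ComparisonResult],
    relpos: pd.DataFrame,
    dunn_results: list[ComparisonResult],
    subregion_percent: Optional[float],
    consistency_percent: Optional[float],
    path: Path | str,
    method_a: str = "leaddbs",
    method_b: str = "surgiplan",
) -> None:
    """Write the human-readable markdown report (coordinate table layout:
    per-axis All/Right/Left rows with mean +/- SD, discrepancy, p)."""
    lines = ["# Electrode reconstruction comparison", ""]
    lines += [
        "## Contact coordinates (mm, AC-PC frame)",
        "",
        f"| Axis | Scope | {method_a} | {method_b} | Mean discrepancy | p |",
        "|---|---|---|---|---|---|",
    ]
    by_key = {(r.axis, r.scope): r for r in results}
    for axis in ("x", "y", "z"):
        for scope in ("all", "right", "left"):
            r = by_key.get((axis, scope))
            if r is None:
                continue
            sd_a = _axis_scope_sd(table, axis, scope, method_a)
            sd_b = _axis_scope_sd(table, axis, scope, method_b)
            lines.append(
                f"| {axis.upper()} | {scope.capitalize()} "
                f"| {r.mean_a:.2f} ± {sd_a:.2f} | {r.mean_b:.2f} ± {sd_b:.2f} "
                f"| {mean_discrepancy(r.mean_a, r.mean_b):.2f} "
                f"| {r.p_value:.4f} |"
            )
    lines.append("")

    lines += ["## Relative distance to the ventral STN border (mm)", ""]
    ok = relpos[relpos["category"] != "above_rn_level"]
    for side in ("right", "left"):
        sub = ok[ok["side"] == side]
        parts = []
        for method in (method_a, method_b):
            vals = sub[sub["method"] == method]["relative_distance_mm"]
            if len(vals):
                parts.append(f"{method} {vals.mean():.2f} ± {vals.std(ddof=1):.2f}")
        lines.append(f"- {side}: " + "; ".join(parts))
    n_above = int(
        (relpos["category"] == "above_rn_level").groupby(
            [relpos["patient_id"], relpos["side"]]
        ).any().sum()
    )
    lines.append(f"- electrodes above the maximum RN level: {n_above}")
    lines.append("")

    if consistency_percent is not None:
        lines.append(
            f"## Between-method position consistency: {consistency_percent:.1f}%"
        )
        lines.append("")
    if subregion_percent is not None:
        lines.append(
            "## Contacts in the dorsolateral STN subregion: "
            f"{subregion_percent:.1f}%"
        )
        lines.append("")

    lines += ["## Tip-to-target distance vs MER depth", ""]
    for r in dunn_results:
        lines.append(
            f"- {r.method_a} vs {r.method_b}: delta={r.mean_discrepancy:.2f} mm, "
            f"{r.test_name} p={r.p_value:.4f}"
        )
    lines.append("")
    Path(path).write_text("\n".join(lines))


def run_pipeline(
    config: SimulationConfig,
    outdir: Path | str,
    seed: Optional[int] = None,
) -> RunManifest:
    """Simulate a cohort and run every analysis stage; write all outputs.

    Returns the saved manifest.  Outputs: anatomy OBJs, ``landmarks.csv``,
    ``mer.csv``, ``contacts.csv``, ``relpos.csv``, ``distances.csv``,
    ``results.csv`` and ``report.md``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = SimulationConfig.from_dict({**config.to_dict(), "seed": int(seed)})

    logger.info("stage: simulate")
    inputs = simulate_to_dir(config, outdir)
    landmarks = pd.read_csv(inputs["landmarks"], dtype={"patient_id": str})
    mer = pd.read_csv(inputs["mer"], dtype={"patient_id": str})
    anatomy = generate_anatomy(config)

    logger.info("stage: contacts")
    contacts = contacts_from_landmarks(landmarks, config.electrode_model)
    contacts_path = outdir / "contacts.csv"
    write_coordinate_csv(contacts, contacts_path)
    table = table_from_contacts(contacts)

    logger.info("stage: relative position")
    relpos = relpos_from_contacts(contacts, anatomy)
    relpos_path = outdir / "relpos.csv"
    relpos.to_csv(relpos_path, index=False, lineterminator="\n")

    logger.info("stage: distances")
    distances = distances_from_contacts(
        contacts, landmarks, mer, config.method_a, config.method_b,
        config.electrode_model,
    )
    distances_path = outdir / "distances.csv"
    write_distances_csv(distances, distances_path)

    logger.info("stage: compare")
    results = [
        paired_axis_test(table, axis, scope, config.method_a, config.method_b)
        for axis in ("x", "y", "z")
        for scope in ("all", "right", "left")
    ]
    dunn = distance_validation(
        [
            DistanceValidationRecord(
                patient_id=r.patient_id,
                side=Hemisphere(r.side),
                euclid_method_a=r.euclid_a_mm,
                euclid_method_b=r.euclid_b_mm,
                mer_distance=r.mer_mm,
            )
            for r in distances.itertuples(index=False)
        ]
    )
    results_path = outdir / "results.csv"
    results_to_frame(results + dunn).to_csv(
        results_path, index=False, lineterminator="\n"
    )

    # between-method positional consistency (electrodes below RN level only)
    piv = relpos.pivot_table(
        index=["patient_id", "side"], columns="method", values="category",
        aggfunc="first",
    ).dropna()
    usable = piv[
        (piv[config.method_a] != "above_rn_level")
        & (piv[config.method_b] != "above_rn_level")
    ]
    consistency = None
    if len(usable):
        _, consistency = consistency_rate(
            list(usable[config.method_a]), list(usable[config.method_b])
        )

    # subregion mapping of the method-A contact nearest the dorsolateral
    # centroid (stands in for the clinically programmed optimal contact,
    # which targets the sensorimotor sweet spot)
    labels = []
    ca = contacts[contacts["method"] == config.method_a]
    for (pid, side), grp in ca.groupby(["patient_id", "side"], sort=True):
        h = Hemisphere(side)
        sweet = anatomy[("STN_dorsolateral", h)].mesh.center_mass
        pts = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        best = pts[np.argmin(np.linalg.norm(pts - sweet, axis=1))]
        labels.append(
            contact_subregion(
                anatomy[("STN", h)],
                anatomy[("STN_dorsolateral", h)],
                Point3.from_array(best),
            )
        )
    subregion = subregion_rate(labels) if labels else None

    report_path = outdir / "report.md"
    write_report(
        table, results, relpos, dunn, subregion, consistency, report_path,
        config.method_a, config.method_b,
    )

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        inputs=inputs,
        outputs={
            "contacts": str(contacts_path),
            "relpos": str(relpos_path),
            "distances": str(distances_path),
            "results": str(results_path),
            "report": str(report_path),
        },
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest.save(outdir / "manifest.json")
    return manifest
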