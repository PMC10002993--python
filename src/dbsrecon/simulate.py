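"""Synthetic cohort generator: anatomy, implants, and paired measurements.

Emulates the statistical structure of a bilateral STN-DBS cohort measured by
two electrode-reconstruction methods:

* ellipsoidal STN per side with its long axis toward the
  posterior-lateral-dorsal pole, a dorsolateral (sensorimotor) subregion
  carved beyond the 60th percentile along that axis, and a spherical red
  nucleus medial-posterior to the STN;
* a planned target at the dorsolateral-subregion centroid, a true implanted
  electrode near it, and an intraoperative MER depth consistent with the
  implanted tip;
* method A ("leaddbs"-like) observing the trajectory landmarks with zero
  bias, method B ("surgiplan"-like) with a systematic per-axis bias of
  (-0.13, -1.16, +0.59) mm (B minus A, magnitude convention), both with
  ~1 mm per-axis Gaussian noise — the scale of between-method discrepancy
  reported for manual-vs-toolbox electrode reconstruction.

Noise and bias perturb the *landmark points* (ventral contact and cranial
point), not the finished contacts, so interpolation error propagation is
exercised.  One master seed drives keyed independent substreams (per stage,
patient and side) so enlarging the cohort never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import trimesh

from .acpc import Hemisphere, Point3
from .atlas import StructureMesh
from .electrode import (
    MEDTRONIC_3389,
    ElectrodeSpec,
    ElectrodeTrajectory,
    average_contacts,
    fit_trajectory,
    interpolate_contacts,
)
from .comparison import PairedCoordinateTable

__all__ = [
    "GroundTruthImplant",
    "MeasurementSet",
    "SimulationConfig",
    "generate_anatomy",
    "generate_implants",
    "generate_measurements",
]

_STAGES = {"implant": 1, "measure_a": 2, "measure_b": 3}
_SIDES = (Hemisphere.RIGHT, Hemisphere.LEFT)


def _rng(seed: int, stage: str, *key: int) -> np.random.Generator:
    """Independent substream keyed by (stage, indices) under one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage], *key))
    )


@dataclass
class SimulationConfig:
    """Anatomy, bias, noise and seed parameters of the synthetic cohort.

    Geometry fields describe the *right* hemisphere in the canonical AC-PC
    frame (PC origin, +X right, +Y anterior, +Z inferior); the left side is
    the mirror image (x negated).  All lengths are millimetres.
    """

    n_patients: int = 26
    seed: int = 0
    # anatomy (right side)
    stn_center: tuple[float, float, float] = (11.0, 9.0, 4.0)
    stn_radii: tuple[float, float, float] = (5.0, 3.0, 2.0)
    #: long-axis direction of the STN ellipsoid, toward the
    #: posterior-lateral-dorsal pole (dorsal = -Z here)
    stn_long_axis: tuple[float, float, float] = (1.0, -1.0, -1.0)
    dorsolateral_percentile: float = 60.0
    rn_center: tuple[float, float, float] = (5.0, 4.5, 2.5)
    rn_radius: float = 2.5
    # implant plan: the stereotactic target is the ventral-STN point where
    # the tip lands, a few mm inferior of the dorsolateral centroid
    target_offset: tuple[float, float, float] = (0.0, 0.0, 3.5)
    entry_cone_deg: float = 5.0
    placement_sigma_mm: float = 0.5
    mer_sigma: float = 0.5
    # measurement model (per-axis SDs; bias is B minus A, magnitude convention)
    bias_b: tuple[float, float, float] = (-0.13, -1.16, 0.59)
    sigma_a: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sigma_b: tuple[float, float, float] = (1.0, 1.0, 1.0)
    method_a: str = "leaddbs"
    method_b: str = "surgiplan"
    cranial_offset_mm: float = 40.0
    mesh_subdivisions: int = 4
    electrode_model: str = MEDTRONIC_3389.model_name

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(r <= 0 for r in self.stn_radii) or self.rn_radius <= 0:
            raise ValueError("structure radii must be positive")
        for sig in (*self.sigma_a, *self.sigma_b, self.mer_sigma,
                    self.placement_sigma_mm):
            if sig < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.entry_cone_deg < 0 or self.entry_cone_deg >= 90:
            raise ValueError("entry_cone_deg must be in [0, 90)")
        if not 0 < self.dorsolateral_percentile < 100:
            raise ValueError("dorsolateral_percentile must be in (0, 100)")

    @property
    def electrode_spec(self) -> ElectrodeSpec:
        from .electrode import BUILTIN_SPECS

        return BUILTIN_SPECS[self.electrode_model]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for k, v in list(kwargs.items()):
            if isinstance(v, list):
                kwargs[k] = tuple(v)
        return cls(**kwargs)


@dataclass
class GroundTruthImplant:
    """One simulated electrode: the unobserved truth behind both methods."""

    patient_id: str
    side: Hemisphere
    true_trajectory: ElectrodeTrajectory
    planned_target: Point3
    true_tip: Point3
    mer_distance: float

    def __post_init__(self) -> None:
        if self.mer_distance < 0:
            raise ValueError("mer_distance must be non-negative")


@dataclass
class MeasurementSet:
    """Output of the measurement simulator.

    ``table`` holds per-electrode averaged contact coordinates per method;
    ``landmarks`` the raw observed landmark points in the coordinate-CSV
    schema (patient_id, side, method, point_role, x_mm, y_mm, z_mm).
    """

    table: PairedCoordinateTable
    landmarks: "object"  # pandas.DataFrame; typed loosely to keep imports light


def _mirror(v: tuple[float, float, float], side: Hemisphere) -> np.ndarray:
    a = np.asarray(v, dtype=float).copy()
    a[0] *= side.sign_x
    return a


def _orthonormal_basis(u: np.ndarray) -> np.ndarray:
    """Columns: u and two completing orthonormal vectors."""
    u = u / np.linalg.norm(u)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return np.column_stack([u, v, w])


def _slice_and_cap(
    mesh: trimesh.Trimesh, plane_normal: np.ndarray, plane_origin: np.ndarray
) -> trimesh.Trimesh:
    """Slice a convex closed mesh with a plane and cap the cut with a fan.

    Keeps the part on the positive-normal side.  The cut cross-section of a
    convex mesh is a single convex loop, so a fan about the loop centroid is
    a valid cap; winding follows the open boundary's directed edges so the
    result stays consistently wound and watertight.
    """
    open_mesh = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=plane_normal, plane_origin=plane_origin, cap=False
    )
    open_mesh = trimesh.Trimesh(
        vertices=open_mesh.vertices, faces=open_mesh.faces, process=True
    )
    faces = open_mesh.faces
    directed = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
    )
    keys = {(int(a), int(b)) for a, b in directed}
    boundary = [e for e in keys if (e[1], e[0]) not in keys]
    if not boundary:
        return open_mesh  # plane missed the mesh
    verts = open_mesh.vertices
    loop_pts = verts[[e[0] for e in boundary]]
    centroid = loop_pts.mean(axis=0)
    c_idx = len(verts)
    cap_faces = np.array([[e[1], e[0], c_idx] for e in boundary])
    capped = trimesh.Trimesh(
        vertices=np.vstack([verts, centroid]),
        faces=np.vstack([faces, cap_faces]),
        process=False,
    )
    if capped.volume < 0:
        capped.invert()
    return capped


def generate_anatomy(config: SimulationConfig) -> dict[tuple[str, Hemisphere], StructureMesh]:
    """Build the six synthetic structures (STN, dorsolateral STN, RN x 2 sides).

    Left-side structures are exact x-mirrored copies of the right side.
    Raises ``ValueError`` if the configured STN and RN volumes overlap.
    """
    out: dict[tuple[str, Hemisphere], StructureMesh] = {}
    for side in _SIDES:
        stn_c = _mirror(config.stn_center, side)
        rn_c = _mirror(config.rn_center, side)
        u = _mirror(config.stn_long_axis, side)
        u = u / np.linalg.norm(u)
        basis = _orthonormal_basis(u)

        unit = trimesh.creation.icosphere(
            subdivisions=config.mesh_subdivisions, radius=1.0
        )
        verts = (unit.vertices * np.asarray(config.stn_radii)) @ basis.T + stn_c
        stn_mesh = trimesh.Trimesh(vertices=verts, faces=unit.faces.copy(),
                                   process=False)
        if stn_mesh.volume < 0:
            stn_mesh.invert()
        stn = StructureMesh(mesh=stn_mesh, label="STN", side=side)

        rn_unit = trimesh.creation.icosphere(
            subdivisions=config.mesh_subdivisions, radius=config.rn_radius
        )
        rn_mesh = trimesh.Trimesh(
            vertices=rn_unit.vertices + rn_c, faces=rn_unit.faces, process=False
        )
        rn = StructureMesh(mesh=rn_mesh, label="RN", side=side)

        # overlap guard: quick bound, then exact vertex containment
        gap = np.linalg.norm(stn_c - rn_c)
        if gap <= max(config.stn_radii) + config.rn_radius:
            if stn.contains(rn.mesh.vertices).any() or rn.contains(
                stn.mesh.vertices
            ).any():
                raise ValueError("configured STN and RN volumes overlap")

        proj = stn_mesh.vertices @ u
        thresh = float(np.percentile(proj, config.dorsolateral_percentile))
        dl_mesh = _slice_and_cap(stn_mesh, plane_normal=u, plane_origin=u * thresh)
        dl = StructureMesh(mesh=dl_mesh, label="STN_dorsolateral", side=side)

        out[("STN", side)] = stn
        out[("RN", side)] = rn
        out[("STN_dorsolateral", side)] = dl
    return out


def _cone_direction(
    rng: np.random.Generator, axis: np.ndarray, half_angle_deg: float
) -> np.ndarray:
    """Uniform random unit vector within a cone about ``axis``."""
    if half_angle_deg <= 0:
        return axis
    cos_min = np.cos(np.deg2rad(half_angle_deg))
    cos_t = rng.uniform(cos_min, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    basis = _orthonormal_basis(axis)
    local = np.array([cos_t, sin_t * np.cos(phi), sin_t * np.sin(phi)])
    return basis @ local


def generate_implants(
    config: SimulationConfig,
    anatomy: dict[tuple[str, Hemisphere], StructureMesh],
) -> list[GroundTruthImplant]:
    """Simulate the planned targets and true implanted electrodes.

    The planned target sits at the dorsolateral-subregion centroid (plus the
    configured offset); the electrode approaches along a typical
    double-oblique trajectory (anterior-superior-lateral shaft direction)
    perturbed within ``entry_cone_deg``; the true tip deviates from plan by
    an isotropic Gaussian of SD ``placement_sigma_mm``; the MER depth is the
    true tip-to-target distance plus Gaussian reading noise, clipped at 0.
    """
    spec = config.electrode_spec
    implants: list[GroundTruthImplant] = []
    for p_idx in range(config.n_patients):
        pid = f"P{p_idx:03d}"
        for s_idx, side in enumerate(_SIDES):
            rng = _rng(config.seed, "implant", p_idx, s_idx)
            dl = anatomy[("STN_dorsolateral", side)]
            target = dl.mesh.center_mass + _mirror(config.target_offset, side)
            base_dir = _mirror((0.25, 0.50, -0.83), side)
            base_dir = base_dir / np.linalg.norm(base_dir)
            direction = _cone_direction(rng, base_dir, config.entry_cone_deg)
            tip = target + rng.normal(0.0, config.placement_sigma_mm, size=3)
            mer = float(np.linalg.norm(tip - target) + rng.normal(0.0, config.mer_sigma))
            mer = max(mer, 0.0)
            ventral = tip + spec.tip_to_center_mm * direction
            traj = ElectrodeTrajectory(
                ventral_contact=Point3.from_array(ventral),
                direction=tuple(direction),
            )
            implants.append(
                GroundTruthImplant(
                    patient_id=pid,
                    side=side,
                    true_trajectory=traj,
                    planned_target=Point3.from_array(target),
                    true_tip=Point3.from_array(tip),
                    mer_distance=mer,
                )
            )
    return implants


def generate_measurements(
    config: SimulationConfig,
    implants: list[GroundTruthImplant],
    seed: Optional[int] = None,
) -> MeasurementSet:
    """Simulate both methods observing every implant.

    Each method observes the two trajectory landmarks (ventral contact
    centre and a cranial point ``cranial_offset_mm`` up the shaft) with
    independent per-axis Gaussian noise; method B additionally carries the
    systematic bias, applied in the magnitude convention (its X component is
    mirrored on the left so "less lateral" means the same thing on both
    sides).  Landmarks are then run through trajectory fitting and contact
    interpolation, and the four contacts averaged per electrode.
    """
    import pandas as pd

    if seed is None:
        seed = config.seed
    spec = config.electrode_spec
    records = []
    landmark_rows = []
    for i, imp in enumerate(implants):
        v_true = imp.true_trajectory.ventral_contact.as_array()
        c_true = v_true + config.cranial_offset_mm * imp.true_trajectory.direction_array()
        bias = np.asarray(config.bias_b, float).copy()
        bias[0] *= imp.side.sign_x
        for method, sigma, offset, stage in (
            (config.method_a, config.sigma_a, np.zeros(3), "measure_a"),
            (config.method_b, config.sigma_b, bias, "measure_b"),
        ):
            rng = _rng(seed, stage, i)
            sig = np.asarray(sigma, float)
            v_obs = v_true + offset + rng.normal(0.0, 1.0, size=3) * sig
            c_obs = c_true + offset + rng.normal(0.0, 1.0, size=3) * sig
            traj = fit_trajectory(
                Point3.from_array(v_obs), Point3.from_array(c_obs)
            )
            cs = interpolate_contacts(traj, spec, side=imp.side)
            mean = average_contacts(cs)
            records.append((imp.patient_id, imp.side, method, mean))
            for role, pt in (("ventral_contact", v_obs), ("cranial_point", c_obs)):
                landmark_rows.append(
                    {
                        "patient_id": imp.patient_id,
                        "side": imp.side.value,
                        "method": method,
                        "point_role": role,
                        "x_mm": float(pt[0]),
                        "y_mm": float(pt[1]),
                        "z_mm": float(pt[2]),
                    }
                )
        landmark_rows.append(
            {
                "patient_id": imp.patient_id,
                "side": imp.side.value,
                "method": "plan",
                "point_role": "planned_target",
                "x_mm": imp.planned_target.x,
                "y_mm": imp.planned_target.y,
                "z_mm": imp.planned_target.z,
            }
        )
    table = PairedCoordinateTable.from_records(records)
    landmarks = pd.DataFrame(
        landmark_rows,
        columns=[
            "patient_id", "side", "method", "point_role", "x_mm", "y_mm", "z_mm",
        ],
    )
    return MeasurementSet(table=table, landmarks=landmarks)
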