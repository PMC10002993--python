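"""Relative electrode/target geometry against subcortical structures.

Implements the relative-position construction used to compare two electrode
reconstructions against the subthalamic nucleus (STN):

1. find the axial level where the red nucleus (RN) cross-section is largest;
2. take the RN cross-section centroid ("RN centre") at that level;
3. intersect the electrode's contact span with that axial plane;
4. shoot a ray from the RN centre through the electrode point and intersect
   it with the *ventral* border of the STN (the far-side crossing with the
   most inferior Z — the ventral border is used because it is the most
   clearly identifiable STN boundary on T2 imaging);
5. the relative distance is the Euclidean distance between the electrode
   point and that STN intersection.

Structures can be closed triangle meshes (:class:`StructureMesh`, backed by
``trimesh``) or axis-aligned analytic spheres/ellipsoids
(:class:`AnalyticEllipsoid`) with exact sections and ray intersections.
Cross-sections are exact plane/surface intersections (polygons, not voxel
masks) so analytic oracles apply.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import shapely.geometry as sgeom
import trimesh

from .acpc import Hemisphere, Point3
from .electrode import ContactSet

__all__ = [
    "AnalyticEllipsoid",
    "MeshValidationError",
    "NoIntersectionError",
    "RelativePositionRecord",
    "STRUCTURE_LABELS",
    "Structure",
    "StructureMesh",
    "contact_subregion",
    "cross_section_centroid",
    "electrode_point_at_level",
    "max_rn_level",
    "position_category",
    "relative_distance",
    "relative_position_record",
    "stn_ventral_intersection",
]

STRUCTURE_LABELS = ("STN", "RN", "STN_dorsolateral", "STN_other")

_SURFACE_EPS = 1e-9


class MeshValidationError(ValueError):
    """A structure surface violates closedness/orientation requirements."""


class NoIntersectionError(ValueError):
    """A requested plane or ray does not meet the structure."""


@dataclass
class StructureMesh:
    """A closed, consistently wound triangle mesh with an anatomical label."""

    mesh: trimesh.Trimesh
    label: str
    side: Hemisphere

    def __post_init__(self) -> None:
        if self.label not in STRUCTURE_LABELS:
            raise ValueError(
                f"label must be one of {STRUCTURE_LABELS}, got {self.label!r}"
            )
        self.validate()

    @classmethod
    def from_vertices_faces(
        cls, vertices: np.ndarray, faces: np.ndarray, label: str, side: Hemisphere
    ) -> "StructureMesh":
        m = trimesh.Trimesh(
            vertices=np.asarray(vertices, float),
            faces=np.asarray(faces, int),
            process=False,
        )
        return cls(mesh=m, label=label, side=side)

    def validate(self) -> None:
        m = self.mesh
        if len(m.faces) == 0 or len(m.vertices) == 0:
            raise MeshValidationError("empty mesh")
        if not m.is_watertight:
            edges = np.sort(m.edges, axis=1)
            _, counts = np.unique(edges, axis=0, return_counts=True)
            n_boundary = int(np.sum(counts != 2))
            raise MeshValidationError(
                f"mesh is not watertight ({n_boundary} edges not shared by "
                "exactly 2 faces)"
            )
        if not m.is_winding_consistent:
            raise MeshValidationError("mesh winding is inconsistent")
        if float(m.area_faces.min()) <= 1e-12:
            raise MeshValidationError("mesh contains degenerate triangles")
        if m.volume < 0:
            # consistently wound but inward-facing; flip once
            m.invert()

    # -- geometry queries -------------------------------------------------

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)

    def z_extent(self) -> tuple[float, float]:
        zs = self.mesh.vertices[:, 2]
        return float(zs.min()), float(zs.max())

    def _section(self, z_level: float):
        return self.mesh.section(
            plane_origin=(0.0, 0.0, z_level), plane_normal=(0.0, 0.0, 1.0)
        )

    def cross_section(self, z_level: float):
        """Planar cross-section at ``z = z_level`` as a shapely geometry (XY), or None.

        Nested loops are combined even-odd so interior loops become holes.
        """
        sec = self._section(z_level)
        if sec is None:
            return None
        polys = []
        for loop in sec.discrete:
            ring = np.asarray(loop)[:, :2]
            if len(ring) < 3:
                continue
            poly = sgeom.Polygon(ring)
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
        if not polys:
            return None
        region = functools.reduce(lambda a, b: a.symmetric_difference(b), polys)
        if region.is_empty or region.area <= 0:
            return None
        return region

    def cross_section_area(self, z_level: float) -> float:
        region = self.cross_section(z_level)
        return 0.0 if region is None else float(region.area)

    def cross_section_centroid_xy(self, z_level: float) -> tuple[float, float]:
        region = self.cross_section(z_level)
        if region is None:
            raise NoIntersectionError(
                f"plane z={z_level} does not intersect {self.label}"
            )
        c = region.centroid
        return float(c.x), float(c.y)

    def cross_section_contains(self, z_level: float, x: float, y: float) -> bool:
        region = self.cross_section(z_level)
        if region is None:
            raise NoIntersectionError(
                f"plane z={z_level} does not intersect {self.label}"
            )
        return bool(region.covers(sgeom.Point(x, y)))

    def ray_hits(
        self, origin: np.ndarray, direction: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All forward ray/surface hits: (t values, points, outward normals).

        Vectorized Moller-Trumbore over every face; hits on a shared edge
        (duplicated across adjacent triangles) are merged.
        """
        origin = np.asarray(origin, float)
        direction = np.asarray(direction, float)
        tri = self.mesh.triangles  # (m, 3, 3)
        v0 = tri[:, 0]
        e1 = tri[:, 1] - v0
        e2 = tri[:, 2] - v0
        h = np.cross(direction, e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > 1e-12
        f = np.zeros_like(a)
        f[ok] = 1.0 / a[ok]
        s = origin - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ direction)
        t = f * np.einsum("ij,ij->i", q, e2)
        eps = 1e-9
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t >= -eps)
        idx = np.flatnonzero(hit)
        if len(idx) == 0:
            return np.empty(0), np.empty((0, 3)), np.empty((0, 3))
        t_hit = t[idx]
        order = np.argsort(t_hit)
        t_hit, idx = t_hit[order], idx[order]
        # merge duplicate hits where the ray crosses a shared edge/vertex
        keep = np.concatenate([[True], np.diff(t_hit) > 1e-9])
        t_hit, idx = t_hit[keep], idx[keep]
        pts = origin + t_hit[:, None] * direction
        return t_hit, pts, self.mesh.face_normals[idx]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Point-in-structure test via the generalized winding number.

        Points on the surface (winding ~0.5) count as inside.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        tri = self.mesh.triangles
        out = np.empty(len(pts), dtype=bool)
        for i, p in enumerate(pts):
            a = tri[:, 0] - p
            b = tri[:, 1] - p
            c = tri[:, 2] - p
            la = np.linalg.norm(a, axis=1)
            lb = np.linalg.norm(b, axis=1)
            lc = np.linalg.norm(c, axis=1)
            numer = np.einsum("ij,ij->i", a, np.cross(b, c))
            denom = (
                la * lb * lc
                + np.einsum("ij,ij->i", a, b) * lc
                + np.einsum("ij,ij->i", b, c) * la
                + np.einsum("ij,ij->i", c, a) * lb
            )
            omega = 2.0 * np.arctan2(numer, denom)
            winding = omega.sum() / (4.0 * np.pi)
            out[i] = winding >= 0.45
        return out


@dataclass
class AnalyticEllipsoid:
    """Axis-aligned ellipsoid (sphere when radii are equal) with exact geometry.

    Used both as an alternative structure representation (JSON analytic
    shapes) and as the exact-geometry path that mesh results are checked
    against.
    """

    center: Point3
    radii: tuple[float, float, float]
    label: str
    side: Hemisphere

    def __post_init__(self) -> None:
        if self.label not in STRUCTURE_LABELS:
            raise ValueError(
                f"label must be one of {STRUCTURE_LABELS}, got {self.label!r}"
            )
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")

    @property
    def volume(self) -> float:
        a, b, c = self.radii
        return float(4.0 / 3.0 * np.pi * a * b * c)

    def z_extent(self) -> tuple[float, float]:
        return self.center.z - self.radii[2], self.center.z + self.radii[2]

    def _section_axes(self, z_level: float) -> Optional[tuple[float, float]]:
        dz = (z_level - self.center.z) / self.radii[2]
        if abs(dz) > 1.0:
            return None
        scale = float(np.sqrt(max(0.0, 1.0 - dz * dz)))
        return self.radii[0] * scale, self.radii[1] * scale

    def cross_section_area(self, z_level: float) -> float:
        axes = self._section_axes(z_level)
        return 0.0 if axes is None else float(np.pi * axes[0] * axes[1])

    def cross_section_centroid_xy(self, z_level: float) -> tuple[float, float]:
        if self._section_axes(z_level) is None:
            raise NoIntersectionError(
                f"plane z={z_level} does not intersect {self.label}"
            )
        return self.center.x, self.center.y

    def cross_section_contains(self, z_level: float, x: float, y: float) -> bool:
        axes = self._section_axes(z_level)
        if axes is None:
            raise NoIntersectionError(
                f"plane z={z_level} does not intersect {self.label}"
            )
        ax, ay = axes
        if ax <= 0 or ay <= 0:  # tangent plane: only the pole point is inside
            return bool(
                abs(x - self.center.x) < 1e-12 and abs(y - self.center.y) < 1e-12
            )
        return ((x - self.center.x) / ax) ** 2 + (
            (y - self.center.y) / ay
        ) ** 2 <= 1.0 + 1e-12

    def ray_hits(
        self, origin: np.ndarray, direction: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exact forward ray hits via the unit-sphere substitution."""
        r = np.asarray(self.radii, float)
        o = (np.asarray(origin, float) - self.center.as_array()) / r
        d = np.asarray(direction, float) / r
        a = d @ d
        b = 2.0 * (o @ d)
        c = o @ o - 1.0
        disc = b * b - 4 * a * c
        if disc < 0:
            return np.empty(0), np.empty((0, 3)), np.empty((0, 3))
        sq = np.sqrt(disc)
        ts = np.array(sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a))))
        ts = ts[ts >= -_SURFACE_EPS]
        if len(ts) == 0:
            return np.empty(0), np.empty((0, 3)), np.empty((0, 3))
        pts = np.asarray(origin, float) + ts[:, None] * np.asarray(direction, float)
        # outward normal of (p-c)/r unit sphere mapped back: grad = 2(p-c)/r^2
        grads = 2.0 * (pts - self.center.as_array()) / (r * r)
        normals = grads / np.linalg.norm(grads, axis=1, keepdims=True)
        return ts, pts, normals

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        q = (pts - self.center.as_array()) / np.asarray(self.radii, float)
        return np.einsum("ij,ij->i", q, q) <= 1.0 + 1e-9

    def to_mesh(self, subdivisions: int = 4) -> StructureMesh:
        """Tessellate into a :class:`StructureMesh` (inscribed icosphere)."""
        m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        m.vertices = m.vertices * np.asarray(self.radii, float) + self.center.as_array()
        return StructureMesh(mesh=m, label=self.label, side=self.side)


Structure = Union[StructureMesh, AnalyticEllipsoid]


@dataclass
class RelativePositionRecord:
    """Per-electrode outcome of the RN-level relative-position construction."""

    rn_level_z: float
    rn_center: Optional[Point3]
    electrode_point: Optional[Point3]
    stn_intersection: Optional[Point3]
    relative_distance: Optional[float]
    category: str  # within|medial|lateral|anterior|posterior|above_rn_level


def max_rn_level(rn: Structure, slice_step: float = 0.1) -> float:
    """Axial level (z, mm) where the RN cross-sectional area is maximal.

    The structure's z-extent is scanned at ``slice_step`` resolution, so the
    returned level is within ``slice_step`` of the true maximum for smooth
    shapes.  Deterministic for a fixed step (first maximum wins).
    """
    if slice_step <= 0:
        raise ValueError("slice_step must be positive")
    z0, z1 = rn.z_extent()
    if not np.isfinite([z0, z1]).all() or (z1 - z0) <= 1e-12:
        raise ValueError("structure has zero z-extent")
    zs = np.arange(z0 + slice_step / 2.0, z1, slice_step)
    if len(zs) == 0:
        zs = np.array([(z0 + z1) / 2.0])
    areas = np.array([rn.cross_section_area(float(z)) for z in zs])
    if areas.max() <= 0:
        raise NoIntersectionError("no non-empty cross-section found")
    return float(zs[int(np.argmax(areas))])


def cross_section_centroid(structure: Structure, z_level: float) -> Point3:
    """Area-weighted centroid of the axial cross-section, at the given level."""
    cx, cy = structure.cross_section_centroid_xy(z_level)
    return Point3(cx, cy, z_level)


def electrode_point_at_level(cs: ContactSet, z_level: float) -> Optional[Point3]:
    """Intersection of the electrode's contact span with the plane ``z = z_level``.

    The span runs from the ventral-most to the dorsal-most contact centre
    and is *not* extrapolated beyond it: when the plane lies outside the
    span (the electrode sits entirely above or below the level, or runs
    parallel off-plane) ``None`` is returned — the "above RN level" flag.
    """
    pts = cs.as_array()
    p0, p1 = pts[0], pts[-1]
    dz = p1[2] - p0[2]
    if abs(dz) < 1e-12:
        if abs(p0[2] - z_level) < 1e-9:
            return Point3.from_array(p0)
        return None
    t = (z_level - p0[2]) / dz
    if t < -1e-9 or t > 1.0 + 1e-9:
        return None
    return Point3.from_array(p0 + np.clip(t, 0.0, 1.0) * (p1 - p0))


def stn_ventral_intersection(
    stn: Structure, rn_center: Point3, electrode_point: Point3
) -> Point3:
    """Ventral-border STN crossing of the RN-centre-to-electrode ray.

    A ray is cast from the RN centre through the electrode point (both on
    the same axial plane).  Among the surface crossings, the *exit*
    crossings (ray leaving the structure) are kept and the one with the
    largest +Z — the most inferior, i.e. on the ventral border — is
    returned; ties resolve to the farthest along the ray.
    """
    if abs(rn_center.z - electrode_point.z) > 1e-6:
        raise ValueError("RN centre and electrode point must share the axial level")
    d = electrode_point.as_array() - rn_center.as_array()
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ValueError("RN centre and electrode point coincide")
    direction = d / n
    t, pts, normals = stn.ray_hits(rn_center.as_array(), direction)
    if len(t) == 0:
        raise NoIntersectionError("ray from RN centre misses the STN")
    exit_mask = (normals @ direction) > 0
    if exit_mask.any():
        t, pts = t[exit_mask], pts[exit_mask]
    # most inferior (largest +Z); among equals the farthest downstream
    order = np.lexsort((t, pts[:, 2]))
    return Point3.from_array(pts[order[-1]])


def relative_distance(electrode_point: Point3, stn_intersection: Point3) -> float:
    """Euclidean electrode-to-STN-border distance in mm."""
    return electrode_point.distance_to(stn_intersection)


def position_category(
    stn: Structure, electrode_point: Point3, z_level: float
) -> str:
    """Categorical electrode position relative to the STN cross-section.

    ``within`` when the point lies inside (or on) the STN cross-section at
    the level; otherwise the dominant axis-wise offset from the
    cross-section centroid: medial/lateral along X (hemisphere-aware),
    anterior/posterior along Y.  Equal offsets resolve to the X category
    (lateral beats anterior).
    """
    inside = stn.cross_section_contains(z_level, electrode_point.x, electrode_point.y)
    if inside:
        return "within"
    cx, cy = stn.cross_section_centroid_xy(z_level)
    dx = electrode_point.x - cx
    dy = electrode_point.y - cy
    if abs(dx) >= abs(dy):
        outward = dx * stn.side.sign_x  # positive = farther from midline
        return "lateral" if outward >= 0 else "medial"
    return "anterior" if dy > 0 else "posterior"


def contact_subregion(
    stn: Structure, dorsolateral: Structure, contact: Point3
) -> str:
    """Classify a contact centre: dorsolateral STN, other STN, or outside.

    Surface points count as inside, mirroring manual assessments where a
    contact touching the border is scored as overlapping.
    """
    p = contact.as_array()[None, :]
    if bool(dorsolateral.contains(p)[0]):
        return "dorsolateral"
    if bool(stn.contains(p)[0]):
        return "other_stn"
    return "outside"


def relative_position_record(
    stn: Structure,
    rn: Structure,
    cs: ContactSet,
    slice_step: float = 0.1,
) -> RelativePositionRecord:
    """Run the full RN-level construction for one electrode."""
    level = max_rn_level(rn, slice_step=slice_step)
    rn_c = cross_section_centroid(rn, level)
    ep = electrode_point_at_level(cs, level)
    if ep is None:
        return RelativePositionRecord(
            rn_level_z=level,
            rn_center=rn_c,
            electrode_point=None,
            stn_intersection=None,
            relative_distance=None,
            category="above_rn_level",
        )
    try:
        inter = stn_ventral_intersection(stn, rn_c, ep)
        dist = relative_distance(ep, inter)
    except NoIntersectionError:
        # ray from the RN centre misses the STN entirely: the categorical
        # position is still well defined from the cross-section geometry
        inter, dist = None, None
    return RelativePositionRecord(
        rn_level_z=level,
        rn_center=rn_c,
        electrode_point=ep,
        stn_intersection=inter,
        relative_distance=dist,
        category=position_category(stn, ep, level),
    )
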