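"""Structure geometry: RN level, centroids, ray construction, categories."""

import numpy as np
import pytest
import trimesh

from dbsrecon.acpc import Hemisphere, Point3
from dbsrecon.atlas import (
    AnalyticEllipsoid,
    MeshValidationError,
    NoIntersectionError,
    StructureMesh,
    contact_subregion,
    cross_section_centroid,
    electrode_point_at_level,
    max_rn_level,
    position_category,
    relative_distance,
    relative_position_record,
    stn_ventral_intersection,
)
from dbsrecon.electrode import MEDTRONIC_3389, fit_trajectory, interpolate_contacts

RIGHT = Hemisphere.RIGHT


def sphere_mesh(center, radius, label="RN", side=RIGHT, subdivisions=3):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    m.vertices += np.asarray(center, float)
    return StructureMesh(mesh=m, label=label, side=side)


def line_sphere_exit_oracle(center, radius, origin, direction):
    """Independent quadratic: farthest forward line-sphere crossing."""
    o = np.asarray(origin, float) - np.asarray(center, float)
    d = np.asarray(direction, float)
    b = 2 * o @ d
    c = o @ o - radius**2
    disc = b * b - 4 * c
    if disc < 0:
        return None
    ts = [(-b - np.sqrt(disc)) / 2, (-b + np.sqrt(disc)) / 2]
    ts = [t for t in ts if t >= 0]
    if not ts:
        return None
    return np.asarray(origin) + max(ts) * d


class TestMaxRNLevel:
    def test_sphere_equator(self):
        rn = sphere_mesh((9, -5, 2), 3.0)
        assert max_rn_level(rn, 0.1) == pytest.approx(2.0, abs=0.1)

    def test_analytic_ellipsoid_center(self):
        e = AnalyticEllipsoid(Point3(1, 2, 0), (2, 2, 6), "RN", RIGHT)
        assert max_rn_level(e, 0.05) == pytest.approx(0.0, abs=0.05)

    def test_two_sphere_union_prefers_larger(self):
        # analytic circle-area oracle: the larger sphere's equator wins
        a = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        a.vertices += (0, 0, 8.0)
        b = trimesh.creation.icosphere(subdivisions=3, radius=3.0)
        m = trimesh.util.concatenate([a, b])
        sm = StructureMesh(mesh=m, label="RN", side=RIGHT)
        assert max_rn_level(sm, 0.1) == pytest.approx(0.0, abs=0.1)

    @pytest.mark.parametrize("cz,step", [(2.0, 0.1), (-3.5, 0.25)])
    def test_error_bounded_by_slice_step(self, cz, step):
        e = AnalyticEllipsoid(Point3(0, 0, cz), (3, 2, 4), "RN", RIGHT)
        assert abs(max_rn_level(e, step) - cz) <= step

    def test_bad_step_rejected(self):
        e = AnalyticEllipsoid(Point3(0, 0, 0), (1, 1, 1), "RN", RIGHT)
        with pytest.raises(ValueError):
            max_rn_level(e, 0.0)


class TestCrossSectionCentroid:
    def test_sphere_center_and_offset_levels(self):
        rn = sphere_mesh((9, -5, 2), 3.0)
        c = cross_section_centroid(rn, 2.0)
        np.testing.assert_allclose(c.as_array(), (9, -5, 2), atol=1e-6)
        c = cross_section_centroid(rn, 3.0)
        np.testing.assert_allclose(c.as_array(), (9, -5, 3), atol=1e-6)

    def test_disjoint_boxes_area_weighted_oracle(self):
        # shoelace/area-weighted oracle on two square cross-sections:
        # centroid = (A1*c1 + A2*c2) / (A1 + A2)
        b1 = trimesh.creation.box(extents=(2, 2, 4))
        b2 = trimesh.creation.box(extents=(4, 4, 4))
        b2.vertices += (10.0, 0, 0)
        sm = StructureMesh(
            mesh=trimesh.util.concatenate([b1, b2]), label="STN", side=RIGHT
        )
        c = cross_section_centroid(sm, 0.0)
        expected_x = (4 * 0.0 + 16 * 10.0) / 20.0
        np.testing.assert_allclose(c.as_array(), (expected_x, 0, 0), atol=1e-8)

    def test_missing_plane_rejected(self):
        rn = sphere_mesh((0, 0, 0), 1.0)
        with pytest.raises(NoIntersectionError):
            cross_section_centroid(rn, 5.0)


class TestElectrodePointAtLevel:
    def _contacts(self, ventral, cranial):
        return interpolate_contacts(
            fit_trajectory(Point3(*ventral), Point3(*cranial)), MEDTRONIC_3389
        )

    def test_vertical_span_hit(self):
        cs = self._contacts((0, 0, 0), (0, 0, 10))
        p = electrode_point_at_level(cs, 3.0)
        np.testing.assert_allclose(p.as_array(), (0, 0, 3), atol=1e-12)

    def test_level_outside_span_flags(self):
        cs = self._contacts((0, 0, 4), (0, 0, 14))  # contacts z in [4, 10]
        assert electrode_point_at_level(cs, 2.0) is None

    def test_oblique_scalar_solve(self):
        cs = self._contacts((0, 0, 0), (6, 3, 6))
        level = 2.5
        p = electrode_point_at_level(cs, level)
        # oracle: p = p0 + t*d with p0_z + t*d_z = level
        d = np.array([6, 3, 6]) / 9.0
        t = level / d[2]
        np.testing.assert_allclose(p.as_array(), t * d, atol=1e-9)

    def test_parallel_off_plane_flags(self):
        cs = self._contacts((0, 0, 1), (10, 0, 1))
        assert electrode_point_at_level(cs, 5.0) is None
        on = electrode_point_at_level(cs, 1.0)
        np.testing.assert_allclose(on.as_array(), (0, 0, 1), atol=1e-12)


class TestVentralIntersection:
    def test_collinear_through_center_hits_exit(self):
        c = np.array([10.0, 5.0, 2.0])
        stn = AnalyticEllipsoid(Point3(*c), (2, 2, 2), "STN", RIGHT)
        rn_c = Point3(2.0, 5.0, 2.0)
        ep = Point3(6.0, 5.0, 2.0)
        hit = stn_ventral_intersection(stn, rn_c, ep)
        np.testing.assert_allclose(hit.as_array(), c + (2, 0, 0), atol=1e-9)

    def test_electrode_point_on_surface(self):
        stn = AnalyticEllipsoid(Point3(10, 5, 2), (2, 2, 2), "STN", RIGHT)
        ep = Point3(12.0, 5.0, 2.0)  # exit surface point along the ray
        hit = stn_ventral_intersection(stn, Point3(2, 5, 2), ep)
        assert relative_distance(ep, hit) == pytest.approx(0.0, abs=1e-9)

    def test_missing_ray_raises(self):
        stn = AnalyticEllipsoid(Point3(10, 5, 2), (2, 2, 2), "STN", RIGHT)
        with pytest.raises(NoIntersectionError):
            stn_ventral_intersection(stn, Point3(2, 20, 2), Point3(6, 20, 2))

    def test_mesh_matches_analytic_within_chordal_error(self):
        center, radius = (10.0, 5.0, 2.0), 2.0
        mesh = sphere_mesh(center, radius, label="STN", subdivisions=4)
        ana = AnalyticEllipsoid(Point3(*center), (2, 2, 2), "STN", RIGHT)
        rn_c, ep = Point3(2, 4, 2), Point3(7, 4.8, 2)
        h_mesh = stn_ventral_intersection(mesh, rn_c, ep)
        h_ana = stn_ventral_intersection(ana, rn_c, ep)
        assert h_mesh.distance_to(h_ana) < 2e-3 * radius

    def test_analytic_matches_quadratic_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            center = rng.uniform(-5, 5, 3)
            radius = rng.uniform(0.5, 3.0)
            z = center[2] + rng.uniform(-0.5, 0.5) * radius
            rn_c = np.array([*(center[:2] + rng.uniform(-8, -4, 2)), z])
            toward = center[:2] - rn_c[:2] + rng.uniform(-0.3, 0.3, 2)
            ep = np.array([*(rn_c[:2] + toward * rng.uniform(0.5, 2.0)), z])
            d = ep - rn_c
            d /= np.linalg.norm(d)
            oracle = line_sphere_exit_oracle(center, radius, rn_c, d)
            stn = AnalyticEllipsoid(
                Point3(*center), (radius,) * 3, "STN", RIGHT
            )
            try:
                hit = stn_ventral_intersection(
                    stn, Point3(*rn_c), Point3(*ep)
                ).as_array()
            except NoIntersectionError:
                assert oracle is None
                continue
            assert oracle is not None
            np.testing.assert_allclose(hit, oracle, atol=1e-6)


class TestRelativeDistanceProperties:
    def test_three_four_five(self):
        assert relative_distance(Point3(0, 0, 0), Point3(3, 4, 0)) == 5.0
        assert relative_distance(Point3(1, 1, 1), Point3(1, 1, 1)) == 0.0

    def test_rigid_invariance(self):
        rng = np.random.default_rng(3)
        A = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(A) < 0:
            A[:, 0] *= -1
        shift = rng.normal(size=3)
        p, q = rng.normal(size=3), rng.normal(size=3)
        d0 = relative_distance(Point3.from_array(p), Point3.from_array(q))
        d1 = relative_distance(
            Point3.from_array(A @ p + shift), Point3.from_array(A @ q + shift)
        )
        assert d0 == pytest.approx(d1, abs=1e-9)

    def test_shrinking_convex_stn_never_decreases_distance(self):
        # electrode point downstream (lateral) of the STN along the ray
        rn_c, ep = Point3(0, 0, 0), Point3(15, 0, 0)
        center = Point3(10, 0.5, 0)
        last = -1.0
        for scale in (1.0, 0.8, 0.6, 0.4):
            stn = AnalyticEllipsoid(center, (2 * scale,) * 3, "STN", RIGHT)
            hit = stn_ventral_intersection(stn, rn_c, ep)
            d = relative_distance(ep, hit)
            assert d >= last - 1e-9
            last = d


class TestPositionCategory:
    stn = AnalyticEllipsoid(Point3(10, 5, 2), (3, 2, 2), "STN", RIGHT)

    def test_inside_is_within(self):
        assert position_category(self.stn, Point3(10.5, 5.2, 2), 2.0) == "within"

    def test_lateral_offset(self):
        assert position_category(self.stn, Point3(15.0, 5.0, 2), 2.0) == "lateral"

    def test_medial_and_left_hemisphere_orientation(self):
        assert position_category(self.stn, Point3(5.0, 5.0, 2), 2.0) == "medial"
        left = AnalyticEllipsoid(Point3(-10, 5, 2), (3, 2, 2), "STN", Hemisphere.LEFT)
        assert position_category(left, Point3(-15.0, 5.0, 2), 2.0) == "lateral"
        assert position_category(left, Point3(-5.0, 5.0, 2), 2.0) == "medial"

    def test_anterior_posterior(self):
        assert position_category(self.stn, Point3(10.0, 9.0, 2), 2.0) == "anterior"
        assert position_category(self.stn, Point3(10.0, 1.0, 2), 2.0) == "posterior"

    def test_equal_offsets_tie_break_to_x_axis(self):
        assert position_category(self.stn, Point3(15.0, 10.0, 2), 2.0) == "lateral"

    def test_no_section_rejected(self):
        with pytest.raises(NoIntersectionError):
            position_category(self.stn, Point3(10, 5, 9), 9.0)


class TestContactSubregion:
    def test_centroid_and_far_point(self, anatomy):
        stn = anatomy[("STN", RIGHT)]
        dl = anatomy[("STN_dorsolateral", RIGHT)]
        c = Point3.from_array(dl.mesh.center_mass)
        assert contact_subregion(stn, dl, c) == "dorsolateral"
        assert contact_subregion(stn, dl, Point3(80, 80, 80)) == "outside"

    def test_mesh_containment_matches_analytic_oracle(self):
        # winding-number containment on a tessellated sphere vs the exact
        # ball inequality, for points clearly off the surface
        center, radius = np.array([1.0, -2.0, 3.0]), 2.0
        sm = sphere_mesh(center, radius, label="STN", subdivisions=4)
        rng = np.random.default_rng(5)
        pts = center + rng.uniform(-1.5, 1.5, size=(200, 3)) * radius
        r = np.linalg.norm(pts - center, axis=1)
        clear = np.abs(r - radius) > 0.05 * radius
        got = sm.contains(pts[clear])
        np.testing.assert_array_equal(got, (r[clear] <= radius))

    def test_surface_point_counts_inside(self):
        sm = sphere_mesh((0, 0, 0), 2.0, label="STN", subdivisions=3)
        v = sm.mesh.vertices[17]
        assert bool(sm.contains(v[None, :])[0])


class TestMeshValidation:
    def test_open_mesh_rejected_with_boundary_count(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        open_mesh = trimesh.Trimesh(
            vertices=box.vertices, faces=box.faces[:-1], process=False
        )
        with pytest.raises(MeshValidationError, match="watertight"):
            StructureMesh(mesh=open_mesh, label="STN", side=RIGHT)

    def test_unknown_label_rejected(self):
        m = trimesh.creation.icosphere(subdivisions=2)
        with pytest.raises(ValueError):
            StructureMesh(mesh=m, label="thalamus", side=RIGHT)


class TestRelativePositionRecord:
    def test_above_level_flag_propagates(self):
        stn = AnalyticEllipsoid(Point3(10, 5, 2), (3, 2, 2), "STN", RIGHT)
        rn = AnalyticEllipsoid(Point3(3, 3, 2), (2, 2, 2), "RN", RIGHT)
        cs = interpolate_contacts(
            fit_trajectory(Point3(9, 5, 20), Point3(9, 5, 30)), MEDTRONIC_3389
        )
        rec = relative_position_record(stn, rn, cs)
        assert rec.category == "above_rn_level"
        assert rec.relative_distance is None

    def test_full_record_geometry(self):
        stn = AnalyticEllipsoid(Point3(10, 5, 2), (3, 2, 2), "STN", RIGHT)
        rn = AnalyticEllipsoid(Point3(3, 3, 2), (2, 2, 2), "RN", RIGHT)
        cs = interpolate_contacts(
            fit_trajectory(Point3(14, 5, 1), Point3(15, 5, 11)), MEDTRONIC_3389
        )
        rec = relative_position_record(stn, rn, cs, slice_step=0.05)
        assert rec.rn_level_z == pytest.approx(2.0, abs=0.05)
        assert rec.category in ("within", "lateral", "medial", "anterior", "posterior")
        assert rec.relative_distance is not None and rec.relative_distance >= 0
        assert rec.relative_distance == pytest.approx(
            rec.electrode_point.distance_to(rec.stn_intersection)
        )
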