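"""Spherical geometry: coordinate conversion, the empty-cap triangulation,
circumcircles, inner angles, and the Voronoi dual."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull

from migpatterns import (
    DegenerateGeometryError,
    GeoPopulation,
    SyntheticConfig,
    angular_distance,
    canonical_code,
    circumcircle,
    delaunay_map,
    delaunay_triangulate,
    dual,
    latlon_to_unit,
    make_tetrahedron,
    random_points,
    voronoi_dual,
)


class TestCoordinates:
    @pytest.mark.parametrize(
        "lon,lat,expected",
        [
            (0.0, 0.0, (1.0, 0.0, 0.0)),
            (90.0, 0.0, (0.0, 1.0, 0.0)),
            (180.0, 0.0, (-1.0, 0.0, 0.0)),
        ],
    )
    def test_axis_cases(self, lon, lat, expected):
        assert np.allclose(latlon_to_unit(lon, lat), expected, atol=1e-12)

    def test_near_pole_limit(self):
        eps = 1e-6
        v = latlon_to_unit(0.0, 90.0 - eps)
        assert np.linalg.norm(v - np.array([0.0, 0.0, 1.0])) < 1e-7

    @pytest.mark.parametrize("lat", [90.0, -90.0, float("nan")])
    def test_degenerate_latitudes_rejected(self, lat):
        with pytest.raises(DegenerateGeometryError):
            latlon_to_unit(0.0, lat)

    def test_longitude_normalized_to_half_open_interval(self):
        assert GeoPopulation("x", 270.0, 0.0).longitude == -90.0
        assert GeoPopulation("x", -180.0, 0.0).longitude == 180.0
        assert GeoPopulation("x", 180.0, 0.0).longitude == 180.0

    @given(
        lon=st.floats(-180, 360, allow_nan=False),
        lat=st.floats(-89.9, 89.9, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_unit_norm(self, lon, lat):
        assert abs(np.linalg.norm(latlon_to_unit(lon, lat)) - 1.0) < 1e-12


class TestAngularDistance:
    def test_orthogonal_and_antipodal(self):
        e1, e2 = np.eye(3)[0], np.eye(3)[1]
        assert angular_distance(e1, e2) == pytest.approx(math.pi / 2)
        assert angular_distance(e1, -e1) == pytest.approx(math.pi)
        assert angular_distance(e1, e1) == 0.0

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError):
            angular_distance(np.array([2.0, 0.0, 0.0]), np.eye(3)[0])

    def test_symmetry_and_triangle_inequality(self, rng):
        x = rng.normal(size=(3, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        d01 = angular_distance(x[0], x[1])
        d12 = angular_distance(x[1], x[2])
        d02 = angular_distance(x[0], x[2])
        assert d01 == pytest.approx(angular_distance(x[1], x[0]))
        assert d02 <= d01 + d12 + 1e-12


class TestTriangulation:
    def test_tetrahedron_all_triples_accepted(self, tetra_populations):
        c = delaunay_triangulate(tetra_populations)
        assert len(c.triangles) == 4
        assert len(c.edges) == 6
        assert c.n_candidates == 4

    def test_sumba_counts(self, sumba_complex):
        assert len(sumba_complex.triangles) == 12
        assert len(sumba_complex.edges) == 18
        assert sumba_complex.n_candidates == 56

    def test_every_edge_has_two_triangles(self, sumba_complex):
        for _, (_, tris) in sumba_complex.edges.items():
            assert len(tris) == 2

    def test_too_few_points_rejected(self):
        pops = [GeoPopulation(f"p{i}", 10.0 * i, 5.0) for i in range(3)]
        with pytest.raises(ValueError, match="at least 4"):
            delaunay_triangulate(pops)

    def test_coincident_points_rejected(self):
        pops = [
            GeoPopulation("a", 0.0, 0.0),
            GeoPopulation("b", 0.0, 0.0),
            GeoPopulation("c", 10.0, 0.0),
            GeoPopulation("d", 0.0, 10.0),
        ]
        with pytest.raises(DegenerateGeometryError):
            delaunay_triangulate(pops)

    def test_cocircular_quadruple_raises_degeneracy(self):
        # four points on a common circle (equal latitude), plus two generic ones
        pops = [GeoPopulation(f"c{i}", 90.0 * i, 30.0) for i in range(4)]
        pops += [GeoPopulation("s", 45.0, -60.0), GeoPopulation("t", 200.0, -10.0)]
        with pytest.raises(DegenerateGeometryError, match="cocircular"):
            delaunay_triangulate(pops)

    @pytest.mark.parametrize("mode,n", [("uniform", 9), ("uniform", 14), ("cap", 9)])
    def test_counts_match_euler_on_random_sets(self, mode, n):
        pops = random_points(SyntheticConfig(n=n, mode=mode, seed=7))
        c = delaunay_triangulate(pops)
        assert len(c.triangles) == 2 * n - 4
        assert len(c.edges) == 3 * n - 6

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_agrees_with_convex_hull_oracle(self, seed):
        """The empty-cap triangle set equals the hull facets of the points."""
        pops = random_points(SyntheticConfig(n=12, mode="uniform", seed=seed))
        c = delaunay_triangulate(pops)
        hull = ConvexHull(np.array([p.xyz for p in pops]))
        assert {tuple(sorted(f)) for f in hull.simplices} == set(c.triangles)


class TestCircumcircle:
    def test_symmetric_triangle_centered_on_pole(self):
        pops = [GeoPopulation(f"p{i}", 120.0 * i, 40.0) for i in range(3)]
        pops.append(GeoPopulation("far", 0.0, -80.0))
        pts = np.array([p.xyz for p in pops])
        circ = circumcircle((0, 1, 2), pts)
        assert np.allclose(circ.center, [0.0, 0.0, 1.0], atol=1e-12)

    def test_equidistant_from_all_vertices(self, sumba_complex):
        for tri, circ in sumba_complex.triangles.items():
            for v in tri:
                d = angular_distance(circ.center, sumba_complex.points[v])
                assert d == pytest.approx(circ.radius, abs=1e-9)

    def test_caps_verified_empty_by_brute_force(self, sumba_complex):
        pts = sumba_complex.points
        for tri, circ in sumba_complex.triangles.items():
            for m in range(len(pts)):
                if m not in tri:
                    assert angular_distance(circ.center, pts[m]) > circ.radius


class TestInnerAngles:
    def test_sumba_angles_match_published_values(self, sumba, sumba_complex):
        pair_lab = sumba_complex.pair_labels()
        for pair, paper_lab in sumba.label_map.items():
            theta = sumba_complex.angles[pair_lab[pair]]
            assert theta == pytest.approx(sumba.printed_theta[paper_lab], abs=1e-4)

    def test_angles_strictly_between_zero_and_pi(self, sumba_complex):
        for theta in sumba_complex.angles.values():
            assert 0.0 < theta < math.pi

    @pytest.mark.parametrize("seed", [11, 12])
    def test_agrees_with_tangent_vector_oracle(self, seed):
        """The law-of-cosines angle equals the angle between the great-circle
        tangents toward the two circumcenters at a shared endpoint."""
        pops = random_points(SyntheticConfig(n=10, mode="uniform", seed=seed))
        c = delaunay_triangulate(pops)
        for (i, j), (lab, (t1, t2)) in c.edges.items():
            p = c.points[i]
            tangents = []
            for circ in (c.triangles[t1], c.triangles[t2]):
                u = circ.center - (circ.center @ p) * p
                tangents.append(u / np.linalg.norm(u))
            direct = math.acos(np.clip(tangents[0] @ tangents[1], -1, 1))
            assert c.angles[lab] == pytest.approx(direct, abs=1e-9)

    @pytest.mark.parametrize(
        "mode,seed", [("uniform", 21), ("uniform", 22), ("cap", 23), ("cap", 24)]
    )
    def test_angle_conservation_two_pi_per_population(self, mode, seed):
        pops = random_points(SyntheticConfig(n=10, mode=mode, seed=seed))
        c = delaunay_triangulate(pops)
        for p in pops:
            total = sum(c.angles[lab] for lab in c.incident_labels(p.name))
            assert total == pytest.approx(2 * math.pi, abs=1e-6)


class TestVoronoiDual:
    def test_sumba_voronoi_counts_and_degrees(self, sumba_complex):
        v = voronoi_dual(sumba_complex)
        assert v.counts() == (12, 18, 8)
        assert all(len(orb) == 3 for orb in v.vertices())

    def test_faces_named_after_populations(self, sumba_complex):
        v = voronoi_dual(sumba_complex)
        assert sorted(set(v.face_names.values())) == sorted(sumba_complex.names)

    def test_dual_of_dual_is_delaunay_map(self, sumba_complex):
        v = voronoi_dual(sumba_complex)
        assert canonical_code(dual(v)) == canonical_code(delaunay_map(sumba_complex))

    def test_tetrahedron_voronoi_is_tetrahedron_map(self, tetra_populations):
        v = voronoi_dual(delaunay_triangulate(tetra_populations))
        assert canonical_code(v) == canonical_code(make_tetrahedron())
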