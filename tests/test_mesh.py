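"""Geometry primitives: projection, lengths, angles, areas, interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retmap.mesh import (FlatMap, MapProjection, Mesh3D, MeshError,
                         barycentric_interpolate, corner_angles, edge_lengths,
                         orthographic_project, triangle_field_sign,
                         uniform_resample, vertex_surface_areas)


def icosahedron():
    phi = (1 + np.sqrt(5)) / 2
    v = np.array([[-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
                  [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
                  [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1]],
                 dtype=float)
    v /= np.linalg.norm(v, axis=1)[:, None]
    f = np.array([[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
                  [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
                  [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
                  [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]])
    return Mesh3D(v, f)


def icosphere(subdiv=2):
    """Subdivided icosahedron projected back to the unit sphere."""
    mesh = icosahedron()
    verts = list(mesh.vertices)
    faces = mesh.faces
    for _ in range(subdiv):
        cache = {}
        new_faces = []

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc],
                          [ab, bc, ca]]
        faces = np.array(new_faces)
    return Mesh3D(np.array(verts), faces)


class TestOrthographicProject:
    def test_center_maps_to_origin_and_equator_to_unit_norm(self):
        mesh = icosphere(2)
        # add the exact center vertex by rotating the projection to hit one
        proj = MapProjection(center=mesh.vertices[0], radius_deg=90.0,
                             chirality="rh")
        fm = orthographic_project(mesh, proj)
        src = fm.vertex_ids.tolist().index(0)
        assert np.allclose(fm.coordinates[src], [0.0, 0.0], atol=1e-12)
        # orthographic: coordinate norm = sin(angle to center)
        ang = np.arccos(np.clip(mesh.vertices[fm.vertex_ids] @
                                mesh.vertices[0], -1, 1))
        assert np.allclose(np.linalg.norm(fm.coordinates, axis=1),
                           np.sin(ang), atol=1e-9)

    def test_retained_count_matches_angle_oracle(self):
        mesh = icosphere(2)  # 642 vertices
        center = np.array([0.0, -1.0, 0.0])
        proj = MapProjection(center=center, radius_deg=60.0)
        fm = orthographic_project(mesh, proj)
        ang = np.degrees(np.arccos(np.clip(mesh.vertices @ center, -1, 1)))
        assert fm.n_vertices == (ang <= 60.0 + 1e-12).sum()

    def test_chirality_flip_mirrors_x(self):
        mesh = icosphere(1)
        p_rh = MapProjection(center=[0, -1, 0], radius_deg=60, chirality="rh")
        p_lh = MapProjection(center=[0, -1, 0], radius_deg=60, chirality="lh")
        rh = orthographic_project(mesh, p_rh)
        lh = orthographic_project(mesh, p_lh)
        assert np.allclose(lh.coordinates[:, 0], -rh.coordinates[:, 0])
        assert np.allclose(lh.coordinates[:, 1], rh.coordinates[:, 1])

    def test_non_spherical_input_rejected(self):
        mesh = icosphere(1)
        bad = Mesh3D(mesh.vertices * np.linspace(1, 2, mesh.n_vertices)[:, None],
                     mesh.faces)
        with pytest.raises(MeshError, match="sphere"):
            orthographic_project(bad, MapProjection())

    def test_projection_near_isometric_at_center(self):
        # points within 1 degree of the center: 2D distance vs arc length
        from scipy.spatial import Delaunay
        angs = np.deg2rad(np.repeat(np.linspace(0.2, 1.0, 5), 12))
        azim = np.tile(np.linspace(0, 2 * np.pi, 12, endpoint=False), 5)
        pts = np.vstack([[0.0, 0.0],
                         np.column_stack([angs * np.cos(azim),
                                          angs * np.sin(azim)])])
        t = np.linalg.norm(pts, axis=1)
        verts = np.column_stack([np.sin(t) * np.where(t > 0, pts[:, 0] / np.where(t > 0, t, 1), 0),
                                 np.sin(t) * np.where(t > 0, pts[:, 1] / np.where(t > 0, t, 1), 0),
                                 np.cos(t)])
        mesh = Mesh3D(verts, Delaunay(pts).simplices)
        proj = MapProjection(center=[0.0, 0.0, 1.0], radius_deg=2.0)
        fm = orthographic_project(mesh, proj)
        src = mesh.vertices[fm.vertex_ids]
        arc = np.arccos(np.clip(src[:, 2], -1, 1))
        flat = np.linalg.norm(fm.coordinates, axis=1)
        nz = arc > 0
        assert np.all(np.abs(flat[nz] - arc[nz]) / arc[nz] < 2e-4)


class TestEdgeAndAngle:
    def test_edge_length_examples(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        E = np.array([[0, 1], [1, 2]])
        assert np.allclose(edge_lengths(coords, E), [5.0, 0.0])

    def test_edge_lengths_match_pairwise_oracle(self, rng):
        coords = rng.random((40, 2)) * 10
        E = np.array([(i, (i * 7 + 3) % 40) for i in range(40) if i != (i * 7 + 3) % 40])
        expect = [np.linalg.norm(coords[u] - coords[v]) for u, v in E]
        assert np.allclose(edge_lengths(coords, E), expect, atol=1e-12)

    def test_corner_angle_examples(self):
        eq = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        triples = np.array([[0, 1, 2], [1, 2, 0], [2, 0, 1]])
        assert np.allclose(corner_angles(eq, triples), np.pi / 3, atol=1e-12)
        rt = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert np.isclose(corner_angles(rt, np.array([[0, 1, 2]]))[0],
                          np.pi / 2)

    def test_degenerate_corner_raises(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(MeshError, match="degenerate"):
            corner_angles(coords, np.array([[0, 1, 2]]))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_angle_sum_is_pi_for_random_triangles(self, seed):
        r = np.random.default_rng(seed)
        tri = r.random((3, 2)) * 10
        u, v = tri[1] - tri[0], tri[2] - tri[0]
        area = 0.5 * (u[0] * v[1] - u[1] * v[0])
        if abs(area) < 1e-6:
            return
        if area < 0:
            tri = tri[::-1]
        triples = np.array([[0, 1, 2], [1, 2, 0], [2, 0, 1]])
        assert abs(corner_angles(tri, triples).sum() - np.pi) < 1e-9


class TestFieldSign:
    def test_identity_and_mirror(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        assert np.all(triangle_field_sign(coords, coords, faces) == 1)
        mirror = coords * np.array([-1.0, 1.0])
        assert np.all(triangle_field_sign(coords, mirror, faces) == -1)

    def test_missing_values_marked_not_raised(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        vis = coords.copy()
        vis[2] = np.nan
        out = triangle_field_sign(coords, vis, np.array([[0, 1, 2]]))
        assert np.isnan(out[0])

    def test_adjacent_synthetic_areas_alternate(self, small_model):
        signs = {a: small_model.area_field_sign(a)
                 for a in ("V1", "V2", "V3", "hV4", "V3a")}
        assert signs["V1"] == -signs["V2"]
        assert signs["V2"] == -signs["V3"]
        assert signs["V3"] == -signs["V3a"] == -signs["hV4"]


class TestVertexAreas:
    def test_single_triangle_equal_thirds(self):
        m = Mesh3D(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]),
                   np.array([[0, 1, 2]]))
        assert np.allclose(vertex_surface_areas(m), 0.5 / 3)

    def test_total_area_conserved_on_icosahedron(self):
        mesh = icosahedron()
        va = vertex_surface_areas(mesh)
        a, b, c = (mesh.vertices[mesh.faces[:, i]] for i in range(3))
        face_area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum()
        assert np.isclose(va.sum(), face_area, rtol=1e-12, atol=1e-9)

    def test_collinear_face_contributes_zero(self):
        m = Mesh3D(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]),
                   np.array([[0, 1, 2]]))
        assert np.allclose(vertex_surface_areas(m), 0.0)


class TestInterpolation:
    @pytest.fixture()
    def irregular(self, rng):
        from scipy.spatial import Delaunay
        pts = rng.random((60, 2)) * 4
        return FlatMap(pts, Delaunay(pts).simplices)

    def test_affine_fields_reproduced_exactly(self, irregular, rng):
        f = 2.0 * irregular.coordinates[:, 0] - 0.5 * irregular.coordinates[:, 1] + 1.0
        # interior queries: face centroids
        q = irregular.coordinates[irregular.faces].mean(axis=1)
        got = barycentric_interpolate(irregular, f, q)
        expect = 2.0 * q[:, 0] - 0.5 * q[:, 1] + 1.0
        assert np.nanmax(np.abs(got - expect)) < 1e-12

    def test_vertex_query_returns_vertex_value(self, irregular, rng):
        f = rng.random(irregular.n_vertices)
        got = barycentric_interpolate(irregular, f, irregular.coordinates[:20])
        assert np.allclose(got, f[:20], atol=1e-9)

    def test_outside_hull_is_missing(self, irregular):
        f = np.ones(irregular.n_vertices)
        got = barycentric_interpolate(irregular, f,
                                      np.array([[99.0, 99.0]]))
        assert np.isnan(got[0])


class TestUniformResample:
    def test_linear_field_survives_resampling(self, rng):
        from scipy.spatial import Delaunay
        pts = rng.random((120, 2)) * 5
        fm = FlatMap(pts, Delaunay(pts).simplices)
        fm.fields["lin"] = 3.0 * pts[:, 0] + 2.0 * pts[:, 1] - 1.0
        fm.fields["const"] = np.full(len(pts), 7.0)
        out = uniform_resample(fm, 0.4)
        expect = 3.0 * out.coordinates[:, 0] + 2.0 * out.coordinates[:, 1] - 1.0
        ok = np.isfinite(out.fields["lin"])
        assert ok.sum() > 20
        assert np.max(np.abs(out.fields["lin"][ok] - expect[ok])) < 1e-9
        assert np.allclose(out.fields["const"][ok], 7.0, atol=1e-9)

    def test_lattice_is_uniform(self, small_model):
        out = uniform_resample(small_model.mesh, 0.35)
        lens = edge_lengths(out.coordinates, out.edges)
        assert np.allclose(lens, 0.35, rtol=1e-6)

    def test_too_coarse_resolution_errors(self, small_model):
        with pytest.raises(MeshError):
            uniform_resample(small_model.mesh, 100.0)
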