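"""Mesh data model, I/O, and the low-level geometric queries."""

import numpy as np
import pytest
import trimesh

from platefit.errors import (
    EmptySectionError,
    MeshFormatError,
    MeshValidationError,
    NotWatertightError,
)
from platefit.mesh_core import (
    PlaneSection,
    TriangleMesh,
    load_mesh,
    nearest_vertex_distance,
    nearest_vertex_distances,
    point_inside_surface,
    points_inside_surface,
    save_mesh,
    section_centroid,
    section_mesh,
    surface_distance,
)


# ---------------------------------------------------------------------------
# Construction and I/O
# ---------------------------------------------------------------------------

TET_VERTS = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


class TestMeshConstruction:
    def test_valid_tetrahedron(self):
        mesh = TriangleMesh.from_arrays(TET_VERTS, TET_FACES)
        assert mesh.n_vertices == 4
        assert len(mesh.faces) == 4
        assert mesh.is_watertight

    def test_out_of_range_face_index_rejected(self):
        faces = np.array([[0, 1, 10]])
        with pytest.raises(MeshValidationError):
            TriangleMesh.from_arrays(TET_VERTS, faces)

    def test_non_finite_vertices_rejected(self):
        verts = TET_VERTS.copy()
        verts[0, 0] = np.nan
        with pytest.raises(MeshValidationError):
            TriangleMesh.from_arrays(verts, TET_FACES)

    def test_degenerate_faces_dropped(self):
        faces = np.vstack([TET_FACES, [[1, 1, 2]]])
        mesh = TriangleMesh.from_arrays(TET_VERTS, faces)
        assert len(mesh.faces) == 4

    def test_all_degenerate_rejected(self):
        with pytest.raises(MeshValidationError):
            TriangleMesh.from_arrays(TET_VERTS, np.array([[0, 0, 1]]))


class TestMeshIO:
    def test_stl_ply_round_trip_same_vertices(self, tmp_path):
        mesh = TriangleMesh.from_arrays(TET_VERTS, TET_FACES, name="tet")
        save_mesh(mesh, tmp_path / "tet.stl")
        save_mesh(mesh, tmp_path / "tet.ply")
        from_stl = load_mesh(tmp_path / "tet.stl")
        from_ply = load_mesh(tmp_path / "tet.ply")
        assert from_stl.n_vertices == 4
        a = np.array(sorted(map(tuple, np.round(from_stl.vertices, 9))))
        b = np.array(sorted(map(tuple, np.round(from_ply.vertices, 9))))
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MeshFormatError):
            load_mesh(tmp_path / "nope.stl")

    def test_unsupported_format(self, tmp_path):
        (tmp_path / "mesh.obj").write_text("v 0 0 0\n")
        with pytest.raises(MeshFormatError):
            load_mesh(tmp_path / "mesh.obj")

    def test_unit_scale_applied(self, tmp_path):
        mesh = TriangleMesh.from_arrays(TET_VERTS, TET_FACES)
        save_mesh(mesh, tmp_path / "tet.stl")
        scaled = load_mesh(tmp_path / "tet.stl", scale=10.0)
        assert np.isclose(scaled.vertices.max(), 10.0)


# ---------------------------------------------------------------------------
# Nearest-vertex distance
# ---------------------------------------------------------------------------

class TestNearestVertexDistance:
    def test_hand_computed_example(self):
        mesh = TriangleMesh.from_arrays(
            [[0, 0, 1], [3, 0, 0], [0, 4, 0]], [[0, 1, 2]])
        d, idx = nearest_vertex_distance([0, 0, 5], mesh)
        assert d == 4.0
        assert idx == 0

    def test_coincident_vertex_is_zero(self):
        mesh = TriangleMesh.from_arrays(TET_VERTS, TET_FACES)
        d, idx = nearest_vertex_distance([0, 0, 1], mesh)
        assert d == 0.0
        assert idx == 3

    def test_tie_broken_by_lowest_index(self):
        # two vertices equidistant from the query point
        mesh = TriangleMesh.from_arrays(
            [[1, 0, 0], [-1, 0, 0], [0, 3, 0]], [[0, 1, 2]])
        for method in ("kdtree", "bruteforce"):
            d, idx = nearest_vertex_distance([0, 0, 0], mesh, method=method)
            assert d == 1.0
            assert idx == 0

    def test_kdtree_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        verts = rng.normal(size=(500, 3)) * 50
        faces = rng.integers(0, 500, size=(300, 3))
        keep = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) \
            & (faces[:, 0] != faces[:, 2])
        mesh = TriangleMesh.from_arrays(verts, faces[keep])
        for point in rng.normal(size=(200, 3)) * 60:
            d_k, i_k = nearest_vertex_distance(point, mesh, method="kdtree")
            d_b, i_b = nearest_vertex_distance(point, mesh, method="bruteforce")
            assert d_k == d_b  # exact, not approximate
            assert i_k == i_b

    def test_batch_matches_scalar(self):
        mesh = TriangleMesh.from_arrays(TET_VERTS, TET_FACES)
        pts = np.array([[0.2, 0.2, 5.0], [3.0, 0, 0]])
        batch = nearest_vertex_distances(pts, mesh)
        singles = [nearest_vertex_distance(p, mesh)[0] for p in pts]
        np.testing.assert_allclose(batch, singles)


# ---------------------------------------------------------------------------
# Containment
# ---------------------------------------------------------------------------

class TestContainment:
    def test_sphere_centre_inside(self, unit_sphere):
        assert point_inside_surface([0, 0, 0], unit_sphere)

    def test_far_point_outside(self, unit_sphere):
        assert not point_inside_surface([2, 0, 0], unit_sphere)

    def test_random_points_match_analytic_radius(self, unit_sphere):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-1.5, 1.5, size=(100, 3))
        r = np.linalg.norm(pts, axis=1)
        # the icosphere is slightly inside the unit sphere (chordal gap);
        # only classify points clearly away from the surface shell
        clear = np.abs(r - 1.0) > 0.02
        inside = points_inside_surface(pts[clear], unit_sphere)
        np.testing.assert_array_equal(inside, r[clear] < 1.0)

    def test_reflection_symmetry(self, unit_sphere):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-1.4, 1.4, size=(40, 3))
        r = np.linalg.norm(pts, axis=1)
        pts = pts[np.abs(r - 1.0) > 0.02]
        a = points_inside_surface(pts, unit_sphere)
        b = points_inside_surface(-pts, unit_sphere)
        np.testing.assert_array_equal(a, b)

    def test_open_mesh_rejected(self):
        mesh = TriangleMesh.from_arrays(TET_VERTS, TET_FACES[:2])
        with pytest.raises(NotWatertightError):
            point_inside_surface([0.1, 0.1, 0.1], mesh)


# ---------------------------------------------------------------------------
# Sections and centroids
# ---------------------------------------------------------------------------

class TestSections:
    def test_cylinder_cross_section_radius(self, cylinder):
        sec = section_mesh(cylinder, [0, 0, 0], [0, 0, 1])
        assert len(sec.loops) == 1
        assert sec.closed[0]
        radii = np.linalg.norm(sec.loops[0][:, :2], axis=1)
        assert np.all(np.abs(radii - 10.0) < 0.05)  # chordal tolerance

    def test_plane_missing_mesh(self, cylinder):
        with pytest.raises(EmptySectionError):
            section_mesh(cylinder, [0, 0, 100.0], [0, 0, 1])

    def test_circular_loop_centroid(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        loop = np.column_stack([5 + 3 * np.cos(t), 3 * np.sin(t),
                                np.zeros_like(t)])
        sec = PlaneSection(plane_point=np.array([5.0, 0, 0]),
                           plane_normal=np.array([0, 0, 1.0]),
                           loops=[loop], closed=[True])
        np.testing.assert_allclose(section_centroid(sec), [5, 0, 0],
                                   atol=1e-6)

    def test_square_loop_centroid(self):
        loop = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], float)
        sec = PlaneSection(plane_point=np.zeros(3),
                           plane_normal=np.array([0, 0, 1.0]),
                           loops=[loop], closed=[True])
        np.testing.assert_allclose(section_centroid(sec), [1, 1, 0],
                                   atol=1e-12)

    def test_ellipse_centroid_and_rotation_invariance(self):
        t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        loop = np.column_stack([4 * np.cos(t) + 1, 2 * np.sin(t) - 3,
                                np.zeros_like(t)])
        sec = PlaneSection(plane_point=np.zeros(3),
                           plane_normal=np.array([0, 0, 1.0]),
                           loops=[loop], closed=[True])
        c0 = section_centroid(sec)
        np.testing.assert_allclose(c0, [1, -3, 0], atol=1e-3)
        # rotating the point ordering must not change the centroid
        sec_rolled = PlaneSection(plane_point=sec.plane_point,
                                  plane_normal=sec.plane_normal,
                                  loops=[np.roll(loop, 17, axis=0)],
                                  closed=[True])
        np.testing.assert_allclose(section_centroid(sec_rolled), c0,
                                   atol=1e-12)

    def test_open_loop_rejected(self):
        from platefit.errors import OpenLoopError
        loop = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        sec = PlaneSection(plane_point=np.zeros(3),
                           plane_normal=np.array([0, 0, 1.0]),
                           loops=[loop], closed=[False])
        with pytest.raises(OpenLoopError):
            section_centroid(sec)

    def test_tube_inner_section_single_loop(self, matched_femur):
        # the canal mesh sectioned mid-diaphysis yields one closed loop
        sec = section_mesh(matched_femur.inner, [0, 0, 200.0], [0, 0, 1])
        assert len(sec.loops) == 1 and sec.closed[0]


# ---------------------------------------------------------------------------
# Surface distance
# ---------------------------------------------------------------------------

class TestSurfaceDistance:
    def test_sign_and_magnitude_on_sphere(self, unit_sphere):
        d = surface_distance(np.array([[0.5, 0, 0], [1.5, 0, 0]]),
                             unit_sphere, signed=True)
        assert d[0] < 0 < d[1]
        assert abs(abs(d[0]) - 0.5) < 0.02
        assert abs(d[1] - 0.5) < 0.02

    def test_point_on_vertex_is_zero(self, unit_sphere):
        v = unit_sphere.vertices[10]
        d = surface_distance(v[None, :], unit_sphere)
        assert abs(d[0]) < 1e-12
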