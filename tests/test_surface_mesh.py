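"""Marker projection, Delaunay connectivity, and face bases."""

import itertools

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import tipwall.forward_simulator as fs
from tipwall import ensemble_analysis as ea
from tipwall.axis_reduction import AxisFrame, optimize_long_axis
from tipwall.surface_mesh import (build_mesh, compactness, delaunay_connectivity,
                                  estimate_tip_radius, mean_triangle_area,
                                  project_markers)


def _frame_x():
    return AxisFrame.from_axis_tip([1.0, 0.0, 0.0], [0.0, 0.0, 0.0])


class TestProjection:
    def test_hemisphere_preserves_azimuthal_order(self):
        frame = AxisFrame.from_axis_tip([1.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        th = np.linspace(-2.5, 2.5, 17)
        cap = np.column_stack([np.full_like(th, 0.7), 0.714 * np.cos(th), 0.714 * np.sin(th)])
        p2 = project_markers(cap, frame, tip_radius=1.0)
        th2 = np.arctan2(p2[:, 1], p2[:, 0])
        steps = np.mod(np.diff(th2), 2 * np.pi)  # azimuth increases (mod wrap)
        assert np.all((steps > 0) & (steps < np.pi))

    def test_cylinder_axial_order_becomes_radial(self):
        frame = _frame_x()
        xs = np.linspace(-4.0, -1.5, 12)
        pts = np.column_stack([xs, np.ones_like(xs), np.zeros_like(xs)])
        p2 = project_markers(pts, frame, tip_radius=1.0)
        r = np.hypot(p2[:, 0], p2[:, 1])
        # farther behind the tip -> larger planar radius, order preserved
        assert np.all(np.diff(r) < 0)

    def test_injective_on_generated_cohorts(self, caul_spec, caul_solution):
        prof = fs.ModulusProfile.constant(5.0)
        for seed in range(6):
            cell = fs.generate_cell(caul_spec, prof, fs.NoiseSpec.preset("low"),
                                    seed=seed, solution=caul_solution)
            frame = optimize_long_axis(cell.outline_turgid)
            tr = estimate_tip_radius(cell.outline_turgid, frame)
            p2 = project_markers(cell.markers_turgid, frame, tip_radius=tr)
            d = np.linalg.norm(p2[:, None] - p2[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() > 1e-6


class TestDelaunay:
    def test_square_gives_two_triangles(self):
        faces = delaunay_connectivity(np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]]))
        assert len(faces) == 2

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            delaunay_connectivity(np.array([[0, 0], [1, 0], [0, 1], [0, 1.0]]))

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            delaunay_connectivity(np.array([[0, 0], [1, 1], [2, 2.0]]))

    def test_empty_circumcircle_property_brute_force(self, rng):
        """O(n^4) oracle: no point inside any face's circumcircle."""
        pts = rng.uniform(size=(12, 2))
        faces = delaunay_connectivity(pts)
        for tri in faces:
            a, b, c = pts[tri]
            # circumcenter
            d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
            ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
            uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
            center = np.array([ux, uy])
            R = np.linalg.norm(a - center)
            for k in range(len(pts)):
                if k in tri:
                    continue
                assert np.linalg.norm(pts[k] - center) >= R - 1e-9


class TestBuildMesh:
    def test_identical_configs_give_equal_bases(self, caul_cell):
        mt = caul_cell.markers_turgid
        frame = optimize_long_axis(caul_cell.outline_turgid)
        tr = estimate_tip_radius(caul_cell.outline_turgid, frame)
        faces = delaunay_connectivity(project_markers(mt, frame, tip_radius=tr))
        mesh = build_mesh(mt, mt, faces, frame_turgid=frame)
        np.testing.assert_allclose(mesh.A, mesh.B, atol=1e-12)

    def test_normals_outward_and_bases_invertible(self, caul_cell):
        mt, mu = caul_cell.markers_turgid, caul_cell.markers_unturgid
        frame = optimize_long_axis(caul_cell.outline_turgid)
        tr = estimate_tip_radius(caul_cell.outline_turgid, frame)
        faces = delaunay_connectivity(project_markers(mt, frame, tip_radius=tr))
        mesh = build_mesh(mu, mt, faces, frame_turgid=frame)
        # connectivity shared across configurations by construction
        assert mesh.A.shape == mesh.B.shape
        dets = np.linalg.det(mesh.A[mesh.usable])
        assert np.all(np.abs(dets) > 1e-10)
        from tipwall.axis_reduction import outward_reference
        cen = mesh.centroids_turgid
        ref = outward_reference(cen, frame, tr)
        dots = np.einsum("ij,ij->i", mesh.normals_turgid, ref)
        assert np.all(dots[mesh.usable] > 0)

    def test_vertex_order_does_not_flip_normal(self):
        frame = _frame_x()
        tri_u = np.array([[0, 0, 1.0], [0.3, 0.2, 1.0], [-0.2, 0.4, 1.0]])
        tri_t = tri_u * 1.1
        for order in ([0, 1, 2], [1, 0, 2]):
            faces = np.array([order])
            mesh = build_mesh(tri_u, tri_t, np.array([[0, 1, 2]]),
                              frame_turgid=AxisFrame.from_axis_tip([0, 0, 1.0], [0, 0, 1.2]))
            assert mesh.normals_turgid[0] @ [0, 0, 1.0] > 0


class TestCompactness:
    def test_equilateral_value(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0.0]])
        assert compactness(v) == pytest.approx(4 * np.pi * (np.sqrt(3) / 4) / 9)

    def test_sliver_tends_to_zero(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0.5, 1e-4, 0.0]])
        assert compactness(v) < 0.01

    def test_invariant_under_rigid_motion_and_scaling(self, rng):
        v = rng.normal(size=(3, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        v2 = 3.7 * v @ q.T + rng.normal(size=3)
        assert compactness(v2) == pytest.approx(compactness(v))


class TestMeanTriangleArea:
    def test_scale_invariance(self, caul_cell):
        mt, mu = caul_cell.markers_turgid, caul_cell.markers_unturgid
        frame = optimize_long_axis(caul_cell.outline_turgid)
        tr = estimate_tip_radius(caul_cell.outline_turgid, frame)
        faces = delaunay_connectivity(project_markers(mt, frame, tip_radius=tr))
        mesh = build_mesh(mu, mt, faces, frame_turgid=frame)
        a1, per1 = mean_triangle_area(mesh, 1.0)
        mesh2 = build_mesh(mu * 2, mt * 2, faces)
        a2, _ = mean_triangle_area(mesh2, 2.0)
        assert a2 == pytest.approx(a1, rel=1e-9)
        assert len(per1) == mesh.usable.sum()

    def test_three_classes_are_separated(self, caul_spec, caul_solution):
        prof = fs.ModulusProfile.constant(5.0)
        means = {}
        for name, (n, d) in ea.MESH_CLASSES.items():
            vals = []
            for seed in range(3):
                cell = fs.generate_cell(caul_spec, prof, fs.NoiseSpec.preset("none"),
                                        seed=seed, solution=caul_solution,
                                        n_subset=n, min_dist=d)
                run = ea.run_single_cell(cell, ea.RunConfig(n_markers=n, min_dist=d))
                vals.append(run.mean_area)
            means[name] = np.mean(vals)
        assert means["small"] < means["medium"] < means["large"]
        assert means["large"] > 1.5 * means["medium"] > 1.5**2 * means["small"]


class TestOffExport:
    def test_round_trip_counts(self, tmp_path):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.2]])
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        from tipwall.surface_mesh import write_off
        path = tmp_path / "mesh.off"
        write_off(path, pts, faces)
        lines = path.read_text().splitlines()
        assert lines[0] == "OFF"
        assert lines[1] == "4 2 0"
        assert len(lines) == 2 + 4 + 2


class TestAgainst3DDelaunay:
    def test_projection_mesh_more_compact_than_3d_surface(self, caul_spec, caul_solution):
        """Sign test over 20 seeds on the median compactness score."""
        prof = fs.ModulusProfile.constant(5.0)

        def med(pts, faces):
            p0, p1, p2 = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
            area = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
            per = (np.linalg.norm(p1 - p0, axis=1) + np.linalg.norm(p2 - p1, axis=1)
                   + np.linalg.norm(p0 - p2, axis=1))
            return float(np.median(4 * np.pi * area / per**2))

        wins = 0
        for seed in range(20):
            cell = fs.generate_cell(caul_spec, prof, fs.NoiseSpec.preset("none"),
                                    seed=seed, solution=caul_solution,
                                    n_subset=110, min_dist=0.22)
            mt = cell.markers_turgid
            frame = optimize_long_axis(cell.outline_turgid)
            tr = estimate_tip_radius(cell.outline_turgid, frame)
            faces = delaunay_connectivity(project_markers(mt, frame, tip_radius=tr))
            surf3d = ConvexHull(mt).simplices
            wins += med(mt, faces) > med(mt, surf3d)
        # binomial sign test: >= 15/20 wins rejects "no better" at p < 0.025
        assert wins >= 15
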