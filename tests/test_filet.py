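import numpy as np
import pytest

from ctcfi.filet import (build_rig, fuse_curvature, project_annotations,
                         render_filet, sweep_rings, visualization_loss)
from ctcfi.phantom import make_tube_mesh, tube_bump_annotations
from ctcfi.surface import Centerline, compute_vertex_curvature


def straight_centerline(length):
    axis = np.column_stack([np.linspace(0, length, 41),
                            np.zeros(41), np.zeros(41)])
    return Centerline(points=axis)


class TestRig:
    def test_eight_cameras_spaced_45_degrees(self):
        rig = build_rig(straight_centerline(80), 40.0, k=8)
        dots = np.einsum("ij,ij->i", rig.looks, np.roll(rig.looks, -1, axis=0))
        np.testing.assert_allclose(np.degrees(np.arccos(np.clip(dots, -1, 1))),
                                   45.0, atol=1e-9)

    def test_principal_axes_perpendicular_to_tangent(self):
        rig = build_rig(straight_centerline(80), 25.0, k=6)
        assert np.abs(rig.looks @ rig.tangent).max() <= 1e-6

    def test_fov_union_covers_full_circle(self):
        rig = build_rig(straight_centerline(80), 40.0, k=8)
        assert rig.k * rig.fov_deg >= 360.0 + 2 * rig.k * 0  # margin included
        assert rig.fov_deg > 360.0 / rig.k

    def test_out_of_range_arc_rejected(self):
        with pytest.raises(ValueError):
            build_rig(straight_centerline(80), 90.0)

    def test_too_few_cameras_rejected(self):
        with pytest.raises(ValueError):
            build_rig(straight_centerline(80), 40.0, k=1)


class TestVisualizationLoss:
    def test_ideal_frontal_view_is_zero(self):
        assert visualization_loss(0.0, 0.0, 10.0, 5.0) == 0.0

    def test_grazing_view_is_total_loss(self):
        assert visualization_loss(0.0, np.pi / 2, 10.0, 5.0) == pytest.approx(1.0)
        assert visualization_loss(0.3, np.pi / 2 + 0.5, 10.0, 5.0) == 1.0

    def test_monotone_in_each_factor(self):
        alphas = np.linspace(0, np.pi / 2 - 0.01, 10)
        phis = np.linspace(0, np.pi / 2 - 0.01, 10)
        ds = np.linspace(5.0, 50.0, 10)
        grid = visualization_loss(alphas[:, None, None], phis[None, :, None],
                                  10.0, ds[None, None, :])
        assert np.all(np.diff(grid, axis=0) >= -1e-12)
        assert np.all(np.diff(grid, axis=1) >= -1e-12)
        assert np.all(np.diff(grid, axis=2) >= -1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            visualization_loss(0.0, 0.0, 10.0, 0.0)


class TestRenderFilet:
    def test_cylinder_curvature_uniform(self, plain_tube_mesh):
        rig = build_rig(straight_centerline(80), 40.0)
        filet = fuse_curvature(render_filet(plain_tube_mesh, rig, 20.0),
                               plain_tube_mesh)
        curv = filet.curvature
        assert curv.std() / abs(curv.mean()) <= 0.05

    def test_bump_lands_at_forward_projected_position(self, tube_mesh_with_bump):
        mesh, cl, annotations, (length, radius) = tube_mesh_with_bump
        rig = build_rig(cl, 40.0)
        filet = fuse_curvature(render_filet(mesh, rig, 20.0), mesh)
        filet = project_annotations(annotations, filet, mesh)
        assert len(filet.boxes) == 1
        x, y, w, h = filet.boxes[0][1]
        col = np.argmin(np.abs(filet.azimuth_deg - 90.0))
        row = np.argmin(np.abs(filet.arc_mm - 40.0))
        assert abs((x + w / 2) - col) <= 10
        assert abs((y + h / 2) - row) <= 10

    def test_ring_face_coverage(self, plain_tube_mesh):
        rig = build_rig(straight_centerline(80), 40.0)
        filet = render_filet(plain_tube_mesh, rig, 20.0)
        cents = plain_tube_mesh.face_centroids
        ring = np.flatnonzero((cents[:, 0] >= filet.ring_range[0])
                              & (cents[:, 0] <= filet.ring_range[1]))
        covered = np.isin(ring, np.unique(filet.cell_map))
        assert covered.mean() >= 0.99

    def test_seam_continuity(self, plain_tube_mesh):
        rig = build_rig(straight_centerline(80), 40.0, k=8)
        filet = fuse_curvature(render_filet(plain_tube_mesh, rig, 20.0),
                               plain_tube_mesh)
        jumps = np.abs(np.diff(filet.curvature, axis=1))
        step = 360.0 / rig.k
        seam_cols = [int(round((step / 2 + i * step))) for i in range(rig.k)]
        seam_cols = [c for c in seam_cols if c < jumps.shape[1]]
        interior = np.ones(jumps.shape[1], dtype=bool)
        interior[seam_cols] = False
        p99 = np.percentile(jumps[:, interior], 99)
        assert jumps[:, seam_cols].max() <= max(p99, 1e-9)

    def test_camera_outside_lumen_rejected(self, plain_tube_mesh):
        far_axis = np.column_stack([np.linspace(0, 80, 41),
                                    np.full(41, 50.0), np.zeros(41)])
        rig = build_rig(Centerline(points=far_axis), 40.0)
        with pytest.raises(ValueError, match="not inside the lumen"):
            render_filet(plain_tube_mesh, rig, 20.0)

    def test_visibility_scores_within_bounds(self, plain_tube_mesh):
        rig = build_rig(straight_centerline(80), 40.0)
        filet = render_filet(plain_tube_mesh, rig, 20.0)
        hit = filet.cell_map >= 0
        assert np.all((filet.vis.loss >= 0) & (filet.vis.loss <= 1))
        assert np.all(filet.vis.distance[hit] > 0)


class TestFuseAndProject:
    def test_fusing_twice_is_idempotent(self, tube_mesh_with_bump):
        mesh, cl, _, _ = tube_mesh_with_bump
        filet = render_filet(mesh, build_rig(cl, 40.0), 20.0)
        once = fuse_curvature(filet, mesh).rgb.copy()
        twice = fuse_curvature(filet, mesh).rgb
        np.testing.assert_array_equal(once, twice)

    def test_bump_red_base_ring_blue(self, tube_mesh_with_bump):
        mesh, cl, annotations, _ = tube_mesh_with_bump
        filet = fuse_curvature(render_filet(mesh, build_rig(cl, 40.0), 20.0), mesh)
        col = np.argmin(np.abs(filet.azimuth_deg - 90.0))
        row = np.argmin(np.abs(filet.arc_mm - 40.0))
        center_px = filet.rgb[row, col]
        assert center_px[0] > center_px[2]      # protrusion on the red pole
        # concave junction at the bump rim: more blue than the wall baseline
        rim_row = np.argmin(np.abs(filet.arc_mm - 44.2))
        rim_px = filet.rgb[rim_row, col]
        wall_px = filet.rgb[2, 0]
        assert rim_px[2] > wall_px[2]

    def test_missing_curvature_rejected(self, tube_mesh_with_bump):
        from ctcfi.phantom import make_tube_mesh

        mesh, cl, _, _ = tube_mesh_with_bump
        bare = make_tube_mesh(80.0, 10.0, [])
        filet = render_filet(bare, build_rig(cl, 40.0), 20.0)
        with pytest.raises(ValueError):
            fuse_curvature(filet, bare)

    def test_no_polyps_no_boxes(self, plain_tube_mesh):
        filet = render_filet(plain_tube_mesh, build_rig(straight_centerline(80), 40.0), 20.0)
        filet = project_annotations([], filet, plain_tube_mesh)
        assert filet.boxes == []

    def test_polyp_outside_ring_not_boxed(self, tube_mesh_with_bump):
        mesh, cl, annotations, _ = tube_mesh_with_bump
        filet = render_filet(mesh, build_rig(cl, 10.0), 15.0)   # ring [2.5, 17.5]
        filet = project_annotations(annotations, filet, mesh)
        assert filet.boxes == []


class TestSweep:
    def test_ring_count_arithmetic(self, plain_tube_mesh):
        frames = sweep_rings(plain_tube_mesh, straight_centerline(80),
                             step_mm=10.0, ring_length_mm=20.0, fuse=False)
        # centers from 10 to 70 in steps of 10
        assert len(frames) == 7

    def test_short_centerline_single_ring(self, plain_tube_mesh):
        cl = straight_centerline(80)
        frames = sweep_rings(plain_tube_mesh, cl, step_mm=200.0,
                             ring_length_mm=100.0, fuse=False)
        assert len(frames) == 1

    def test_every_face_covered_at_half_overlap(self, plain_tube_mesh):
        frames = sweep_rings(plain_tube_mesh, straight_centerline(80),
                             step_mm=10.0, ring_length_mm=20.0, fuse=False)
        seen = np.unique(np.concatenate([f.cell_map.ravel() for f in frames]))
        seen = seen[seen >= 0]
        # faces well inside the tube (ends are half-covered by construction)
        cents = plain_tube_mesh.face_centroids
        interior = np.flatnonzero((cents[:, 0] > 1.0) & (cents[:, 0] < 79.0))
        assert np.isin(interior, seen).mean() >= 0.99

    def test_each_polyp_boxed_in_some_frame(self, tube_mesh_with_bump):
        mesh, cl, annotations, _ = tube_mesh_with_bump
        frames = sweep_rings(mesh, cl, truth=annotations)
        boxed = {pid for f in frames for pid, _ in f.boxes}
        assert boxed == {0}
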