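"""Centerline alignment, slice maps, displacement fields and label warping."""

import numpy as np
import pytest

from vesselwarp import (
    Centerline,
    LabelVolume,
    PhantomSpec,
    align_centerlines,
    build_slice_map,
    centerline_from_label,
    forward_field,
    invert_field,
    make_phantom,
    warp_labels,
)
from vesselwarp.centerline import directed_max_distance
from vesselwarp.warp import Grid, DisplacementField, default_target_grid, measure_cross_section_area


def straight_centerline(length=20.0, n=101):
    z = np.linspace(0, length, n)
    return Centerline(points=np.column_stack([np.zeros(n), np.zeros(n), z]))


def cylinder_volume(radius=2.0, length=20.0, spacing=0.2, offset=(0.0, 0.0)):
    n_xy = int(2 * (radius + 1.0) / spacing) | 1
    half = (n_xy - 1) / 2 * spacing
    nz = int(length / spacing) + 1
    x = np.arange(n_xy) * spacing - half
    xx, yy = np.meshgrid(x, x, indexing="ij")
    mask = np.hypot(xx - offset[0], yy - offset[1]) <= radius
    arr = np.zeros((n_xy, n_xy, nz), dtype=np.uint8)
    arr[mask] = 1
    return LabelVolume(array=arr, spacing=np.full(3, spacing), origin=np.array([-half, -half, 0.0]))


class TestCenterlineFromLabel:
    def test_centered_cylinder_gives_grid_axis(self):
        cl = centerline_from_label(cylinder_volume())
        assert np.abs(cl.points[:, :2]).max() < 0.1  # half a voxel

    def test_translation_equivariance(self):
        cl0 = centerline_from_label(cylinder_volume())
        cl1 = centerline_from_label(cylinder_volume(offset=(1.0, 0.0)))
        shift = cl1.points[:, :2] - cl0.points[:, :2]
        assert np.allclose(shift, [1.0, 0.0], atol=1e-9)

    def test_crescent_matches_polygon_centroid_oracle(self):
        # crescent = disk minus offset disk; compare with the shoelace
        # centroid of the same shape computed from dense polygons
        spacing = 0.02
        n = 301
        half = (n - 1) / 2 * spacing
        x = np.arange(n) * spacing - half
        xx, yy = np.meshgrid(x, x, indexing="ij")
        mask = (np.hypot(xx, yy) <= 2.0) & (np.hypot(xx - 1.0, yy) > 1.2)
        arr = np.zeros((n, n, 3), dtype=np.uint8)
        arr[mask] = 1
        vol = LabelVolume(array=arr, spacing=np.full(3, spacing), origin=np.array([-half, -half, 0.0]))
        cl = centerline_from_label(vol)
        # oracle: exact polygon centroid of the crescent (disk difference)
        from shapely.geometry import Point

        crescent = Point(0, 0).buffer(2.0, quad_segs=512) - Point(1.0, 0).buffer(1.2, quad_segs=512)
        assert cl.points[0, 0] == pytest.approx(crescent.centroid.x, abs=0.5 * spacing)
        assert cl.points[0, 1] == pytest.approx(crescent.centroid.y, abs=0.5 * spacing)

    def test_empty_interior_slice_raises(self):
        vol = cylinder_volume()
        arr = vol.array.copy()
        arr[:, :, 50] = 0
        broken = LabelVolume(array=arr, spacing=vol.spacing, origin=vol.origin)
        with pytest.raises(ValueError, match="empty slice"):
            centerline_from_label(broken)


class TestAlignCenterlines:
    def test_identity_for_identical_centerlines(self):
        cl = straight_centerline()
        al = align_centerlines(cl, cl)
        assert al.rigid.angle_deg == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(al.rigid.translation, 0.0, atol=1e-9)
        assert al.arc_map(7.5) == pytest.approx(7.5)

    def test_recovers_known_rigid_motion(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 1, 200)
        pts = np.column_stack([5 * np.sin(t * 2), t * 40, np.cos(t * 3)])
        cl = Centerline(points=pts)
        theta = 0.4
        rot = np.array(
            [[np.cos(theta), 0, np.sin(theta)], [0, 1, 0], [-np.sin(theta), 0, np.cos(theta)]]
        )
        shift = np.array([3.0, -2.0, 7.0])
        moved = cl.transformed(rot, shift)
        al = align_centerlines(cl, moved)
        assert np.allclose(al.rigid.rotation, rot, atol=1e-6)
        assert np.allclose(al.rigid.translation, shift, atol=1e-6)

    def test_piecewise_linear_landmark_map(self):
        cl_a = straight_centerline(length=30.0)
        cl_b = straight_centerline(length=33.0)
        al = align_centerlines(cl_a, cl_b, landmark_pairs=[(0.0, 0.0), (30.0, 33.0)])
        assert al.arc_map(15.0) == pytest.approx(16.5)

    def test_non_monotone_landmarks_raise(self):
        cl = straight_centerline()
        with pytest.raises(ValueError, match="monotone|increasing"):
            align_centerlines(cl, cl, landmark_pairs=[(0.0, 0.0), (10.0, 8.0), (5.0, 12.0)])


class TestBuildSliceMap:
    def test_straight_to_straight_identity(self):
        cl = straight_centerline()
        al = align_centerlines(cl, cl)
        smap = build_slice_map(cl, cl, al)
        assert np.allclose(smap.rotations, np.eye(3), atol=1e-12)
        assert np.allclose(smap.target_points, smap.source_points, atol=1e-12)

    def test_slice_normals_match_arc_tangents(self):
        src = straight_centerline(length=40.0, n=201)
        arc = make_phantom(
            PhantomSpec(centerline_kind="arc", length=40.0, radius=2.0, bend_radius=60.0)
        ).centerline
        al = align_centerlines(src, arc)
        smap = build_slice_map(src, arc, al, anchor_smooth_mm=0.0)
        for i in range(0, 201, 20):
            s = smap.target_s[i]
            phi = s / 60.0
            analytic = np.array([np.sin(phi), 0.0, np.cos(phi)])
            normal = smap.rotations[i][:, 2]
            angle = np.degrees(np.arccos(np.clip(np.dot(normal, analytic), -1, 1)))
            assert angle < 0.1

    def test_no_twist_on_straight_target(self):
        cl = straight_centerline()
        al = align_centerlines(cl, cl)
        smap = build_slice_map(cl, cl, al)
        in_plane = smap.rotations[:, :2, :2]
        # in-plane rotation angle of every pose is zero on a straight target
        angles = np.degrees(np.arctan2(in_plane[:, 1, 0], in_plane[:, 0, 0]))
        assert np.abs(angles).max() < 1e-9

    def test_out_of_range_correspondence_raises(self):
        src = straight_centerline(length=40.0)
        tgt = straight_centerline(length=20.0)
        al = align_centerlines(src, tgt, landmark_pairs=[(0.0, 0.0), (40.0, 40.0)])
        with pytest.raises(ValueError, match="range"):
            build_slice_map(src, tgt, al)


class TestForwardField:
    def test_identity_map_zero_field(self):
        vol = cylinder_volume()
        cl = centerline_from_label(vol)
        smap = build_slice_map(cl, cl, align_centerlines(cl, cl))
        fwd = forward_field(vol, smap)
        assert np.abs(fwd.vectors[fwd.mask]).max() < 1e-9

    def test_pure_translation_constant_field(self):
        vol = cylinder_volume()
        cl = centerline_from_label(vol)
        moved = Centerline(
            points=cl.points + np.array([0.0, 0.0, 5.0]),
            arc_length=cl.arc_length.copy(),
            tangents=cl.tangents.copy(),
        )
        smap = build_slice_map(cl, moved, align_centerlines(cl, moved))
        fwd = forward_field(vol, smap)
        assert np.allclose(fwd.vectors[fwd.mask], [0.0, 0.0, 5.0], atol=1e-9)

    def test_arc_map_matches_closed_form_bending(self):
        # closed-form circular bend in the x-z plane: a voxel at (x, y, z)
        # maps to c(z) + x*n(z) + y*b(z) with the analytic arc frame
        vol = cylinder_volume(radius=2.0, length=20.0, spacing=0.2)
        cl = centerline_from_label(vol)
        rb = 80.0
        arc = make_phantom(
            PhantomSpec(centerline_kind="arc", length=20.0, radius=2.0, bend_radius=rb)
        ).centerline
        al = align_centerlines(cl, arc)
        smap = build_slice_map(cl, arc, al, anchor_smooth_mm=0.0)
        fwd = forward_field(vol, smap)
        ii, jj, kk = np.nonzero(fwd.mask)
        pts = vol.origin + np.column_stack([ii, jj, kk]) * vol.spacing
        # in-plane offsets are taken about the measured slice anchors (the
        # voxel centroid sits ~1e-2 mm off the grid axis from discretization)
        anchors = smap.source_points[kk]
        phi = smap.target_s[kk] / rb
        c = np.column_stack([rb * (1 - np.cos(phi)), np.zeros_like(phi), rb * np.sin(phi)])
        n = np.column_stack([np.cos(phi), np.zeros_like(phi), -np.sin(phi)])
        b = np.tile([0.0, 1.0, 0.0], (len(phi), 1))
        dx = (pts[:, 0] - anchors[:, 0])[:, None]
        dy = (pts[:, 1] - anchors[:, 1])[:, None]
        expected = c + dx * n + dy * b - pts
        got = fwd.vectors[ii, jj, kk]
        assert np.abs(got - expected).max() < 1e-6

    def test_tight_bend_rejected(self):
        vol = cylinder_volume(radius=2.0, length=20.0, spacing=0.2)
        cl = centerline_from_label(vol)
        arc = make_phantom(
            PhantomSpec(centerline_kind="arc", length=20.0, radius=2.0, bend_radius=8.0)
        ).centerline
        al = align_centerlines(cl, arc)
        smap = build_slice_map(cl, arc, al)
        with pytest.raises(ValueError, match="bend radius"):
            forward_field(vol, smap)


class TestInvertField:
    def test_zero_forward_zero_inverse(self):
        vol = cylinder_volume()
        cl = centerline_from_label(vol)
        smap = build_slice_map(cl, cl, align_centerlines(cl, cl))
        fwd = forward_field(vol, smap)
        inv = invert_field(fwd)
        assert np.abs(inv.vectors[inv.mask]).max() < 1e-9

    def test_constant_translation_inverse_is_negation(self):
        vol = cylinder_volume()
        cl = centerline_from_label(vol)
        moved = Centerline(
            points=cl.points + np.array([0.0, 0.0, 5.0]),
            arc_length=cl.arc_length.copy(),
            tangents=cl.tangents.copy(),
        )
        smap = build_slice_map(cl, moved, align_centerlines(cl, moved))
        fwd = forward_field(vol, smap)
        inv = invert_field(fwd)
        assert np.allclose(inv.vectors[inv.mask], [0.0, 0.0, -5.0], atol=1e-6)

    def test_arc_composition_residual_below_tenth_voxel(self, straight_to_arc_warp):
        inv = straight_to_arc_warp["inverse"]
        voxel = float(np.min(inv.grid.spacing))
        assert inv.residual["max_mm"] < 0.1 * voxel

    def test_wrong_direction_rejected(self, straight_to_arc_warp):
        inv = straight_to_arc_warp["inverse"]
        with pytest.raises(ValueError, match="forward"):
            invert_field(inv)


class TestWarpLabels:
    def test_identity_warp_preserves_labels(self):
        vol = cylinder_volume()
        cl = centerline_from_label(vol)
        smap = build_slice_map(cl, cl, align_centerlines(cl, cl))
        fwd = forward_field(vol, smap)
        inv = invert_field(fwd)
        warped = warp_labels(vol, inv)
        assert warped.labeled_volume_mm3() == pytest.approx(vol.labeled_volume_mm3(), rel=0.01)

    def test_arc_warp_preserves_cross_section_areas(self, straight_to_arc_warp):
        warped = straight_to_arc_warp["warped"]
        xray_cl = straight_to_arc_warp["xray_cl"]
        for s in (10.0, 20.0, 30.0):
            area = measure_cross_section_area(warped, xray_cl, s, pixel=0.04)
            assert area == pytest.approx(np.pi * 4.0, rel=0.02)

    def test_rigid_warp_preserves_total_volume_within_1pct(self, straight_to_arc_warp):
        iso, warped = straight_to_arc_warp["iso"], straight_to_arc_warp["warped"]
        assert warped.labeled_volume_mm3() == pytest.approx(iso.labeled_volume_mm3(), rel=0.01)

    def test_false_lumen_ratio_conserved(self, dissection_warp):
        iso, warped = dissection_warp["iso"], dissection_warp["warped"]
        r_src = (iso.array == 2).sum() / (iso.array > 0).sum()
        r_tgt = (warped.array == 2).sum() / (warped.array > 0).sum()
        assert r_tgt == pytest.approx(r_src, rel=0.02)

    def test_centerline_round_trip_within_one_voxel(self, straight_to_arc_warp):
        warped = straight_to_arc_warp["warped"]
        xray_cl = straight_to_arc_warp["xray_cl"]
        rt = centerline_from_label(warped)
        voxel = float(np.min(warped.spacing))
        assert directed_max_distance(rt.points, xray_cl.resample(4000).points) < voxel
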