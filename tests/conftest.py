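"""Shared fixtures: phantoms, projections and warp products.

Expensive geometry is built once per session; tests treat fixtures as
read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from vesselwarp import (
    BoundarySpline,
    Dissection,
    PhantomSpec,
    align_centerlines,
    build_slice_map,
    calibrate_view,
    centerline_from_label,
    extract_centerline,
    forward_field,
    ideal_projection_geometry,
    invert_field,
    make_phantom,
    project_phantom,
    resample_volume,
    triangulate_boundaries,
    warp_labels,
)
from vesselwarp.biplane import Side, View
from vesselwarp.warp import default_target_grid


@pytest.fixture(scope="session")
def cylinder_truth():
    """Straight tube r=2 mm, L=50 mm with analytic ground truth."""
    return make_phantom(PhantomSpec(centerline_kind="straight", length=50.0, radius=2.0, seed=1))


@pytest.fixture(scope="session")
def biplane_geoms():
    ga = ideal_projection_geometry(0.0, target=(0.0, 0.0, 25.0))
    gb = ideal_projection_geometry(90.0, target=(0.0, 0.0, 25.0))
    return ga, gb


def reconstruct_centerline(truth, geoms, n_samples=200, smoothing=0.1):
    """Noise-free biplane reconstruction: project, calibrate, triangulate."""
    va, vb = project_phantom(truth, geoms[0], geoms[1], noise_px=0.0)
    geom_a = calibrate_view(truth.fiducials_3d, va.fiducials_px)
    geom_b = calibrate_view(truth.fiducials_3d, vb.fiducials_px)
    splines = [
        BoundarySpline(va.boundary_left_px, Side.LEFT, View.A),
        BoundarySpline(va.boundary_right_px, Side.RIGHT, View.A),
        BoundarySpline(vb.boundary_left_px, Side.LEFT, View.B),
        BoundarySpline(vb.boundary_right_px, Side.RIGHT, View.B),
    ]
    left, right = triangulate_boundaries(splines, geom_a, geom_b, n_samples=n_samples)
    return extract_centerline(left, right, smoothing=smoothing), (geom_a, geom_b), (left, right)


@pytest.fixture(scope="session")
def cylinder_recon(cylinder_truth, biplane_geoms):
    return reconstruct_centerline(cylinder_truth, biplane_geoms)


@pytest.fixture(scope="session")
def arc_truth():
    """90-degree arc, bend radius 50 mm, lumen radius 2 mm."""
    length = 50.0 * np.pi / 2.0
    return make_phantom(
        PhantomSpec(centerline_kind="arc", length=length, radius=2.0, bend_radius=50.0, seed=1)
    )


@pytest.fixture(scope="session")
def straight_to_arc_warp():
    """Straight cylinder warped onto an analytic 60 mm-radius arc."""
    spec = PhantomSpec(centerline_kind="straight", length=40.0, radius=2.0, seed=2)
    truth = make_phantom(spec, voxel_size=(0.05, 0.05, 0.2))
    iso = resample_volume(truth.label_volume, 0.12)
    xray_cl = make_phantom(
        PhantomSpec(centerline_kind="arc", length=40.0, radius=2.0, bend_radius=60.0, seed=2)
    ).centerline
    oct_cl, idx = centerline_from_label(iso, return_indices=True)
    alignment = align_centerlines(oct_cl, xray_cl)
    smap = build_slice_map(oct_cl, xray_cl, alignment, source_z_index=idx)
    fwd = forward_field(iso, smap)
    inv = invert_field(fwd, default_target_grid(fwd))
    warped = warp_labels(iso, inv)
    return {
        "iso": iso,
        "oct_cl": oct_cl,
        "xray_cl": xray_cl,
        "slice_map": smap,
        "forward": fwd,
        "inverse": inv,
        "warped": warped,
    }


@pytest.fixture(scope="session")
def dissection_warp():
    """Dissected cylinder (flap out of the bend plane) warped onto the arc."""
    spec = PhantomSpec(
        centerline_kind="straight",
        length=40.0,
        radius=2.0,
        seed=7,
        dissection=Dissection(
            start_mm=12.0, end_mm=28.0, angular_extent_deg=90.0, gap_mm=0.4, angle_center_deg=90.0
        ),
    )
    truth = make_phantom(spec, voxel_size=(0.05, 0.05, 0.2))
    iso = resample_volume(truth.label_volume, 0.12)
    xray_cl = make_phantom(
        PhantomSpec(centerline_kind="arc", length=40.0, radius=2.0, bend_radius=60.0, seed=7)
    ).centerline
    oct_cl, idx = centerline_from_label(iso, return_indices=True)
    alignment = align_centerlines(oct_cl, xray_cl)
    smap = build_slice_map(oct_cl, xray_cl, alignment, source_z_index=idx)
    fwd = forward_field(iso, smap)
    inv = invert_field(fwd, default_target_grid(fwd))
    warped = warp_labels(iso, inv)
    return {"truth": truth, "iso": iso, "xray_cl": xray_cl, "inverse": inv, "warped": warped}
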