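"""Synthetic vessel phantoms with known ground truth.

A phantom is a tube swept along an analytic centerline (straight, arc,
helix, or a spline through control points) with an arc-length radius
profile that may include a stenosis and a dissection flap.  The
dissection is modeled as a circumferential shell: a false-lumen channel
of uniform radial gap, separated from the true lumen by a thin membrane
over a limited angular extent and arc-length window.  Phantoms can be
rendered as (a) biplane pinhole projections with fiducial detections
and silhouette boundary traces, and (b) OCT-like stacks of per-frame
lumen contours, so every downstream reconstruction stage can be tested
against analytic truth.

Conventions: right-handed world coordinates in mm; frame 0 of the OCT
stack is the distal end of the region of interest (the imaging catheter
starts distal and is pulled back proximally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .biplane import ProjectionGeometry, check_view_separation
from .centerline import Centerline
from .meshing import TaggedMesh, swept_tube_mesh
from .octstack import FALSE_LUMEN, TRUE_LUMEN, ContourSet, FrameQuality, LabelVolume


@dataclass
class Stenosis:
    """Smooth focal narrowing: ``severity`` is the fractional radius loss."""

    position: float = 0.5  # fraction of total length
    severity: float = 0.5  # fraction of radius lost at the throat
    length: float = 10.0  # mm, full width of the cosine-bump narrowing

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity < 1.0:
            raise ValueError("stenosis severity must be in [0, 1)")
        if not 0.0 <= self.position <= 1.0:
            raise ValueError("stenosis position must be a fraction of length in [0, 1]")
        if self.length <= 0:
            raise ValueError("stenosis length must be positive")


@dataclass
class Dissection:
    """Circumferential shell flap forming a false lumen.

    The false lumen occupies the annular sector
    ``radius + membrane <= rho <= radius + membrane + gap`` over
    ``angular_extent_deg`` degrees, for arc lengths in
    ``[start_mm, end_mm]``; ``membrane`` is the flap thickness keeping
    true and false lumen disjoint.
    """

    start_mm: float
    end_mm: float
    angular_extent_deg: float = 90.0
    gap_mm: float = 0.3
    membrane_mm: float = 0.15
    angle_center_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.end_mm <= self.start_mm:
            raise ValueError("dissection end must exceed start")
        if not 0.0 < self.angular_extent_deg <= 180.0:
            raise ValueError("dissection angular extent must be in (0, 180] degrees")
        if self.gap_mm <= 0 or self.membrane_mm <= 0:
            raise ValueError("dissection gap and membrane must be positive")


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic vessel."""

    centerline_kind: str = "straight"  # straight | arc | helix | spline
    length: float = 50.0  # mm
    radius: float = 2.0  # mm, baseline lumen radius
    stenosis: Optional[Stenosis] = None
    dissection: Optional[Dissection] = None
    bend_radius: float = 50.0  # mm, arc and helix
    helix_pitch: float = 20.0  # mm per turn
    control_points: Optional[np.ndarray] = None  # spline kind
    fiducial_layout: Optional[np.ndarray] = None  # (n, 3) mm; default: 8-corner cage
    detection_sigma_px: float = 0.0
    contour_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("phantom length must be positive")
        if self.radius <= 0:
            raise ValueError("phantom radius must be positive")
        if self.centerline_kind not in ("straight", "arc", "helix", "spline"):
            raise ValueError(f"unknown centerline kind {self.centerline_kind!r}")
        if self.centerline_kind == "spline" and self.control_points is None:
            raise ValueError("spline centerline requires control_points")
        if self.stenosis and self.stenosis.severity > 0:
            if self.radius * (1 - self.stenosis.severity) <= 0:
                raise ValueError("radius must stay positive through the stenosis")
        if self.detection_sigma_px < 0 or self.contour_sigma_mm < 0:
            raise ValueError("noise sigmas must be non-negative")

    def radius_at(self, s: np.ndarray | float) -> np.ndarray:
        """Lumen radius (mm) as a function of arc length (mm)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        r = np.full_like(s, self.radius)
        if self.stenosis is not None and self.stenosis.severity > 0:
            s0 = self.stenosis.position * self.length
            half = self.stenosis.length / 2.0
            in_bump = np.abs(s - s0) < half
            bump = np.zeros_like(s)
            bump[in_bump] = 0.5 * (1.0 + np.cos(np.pi * (s[in_bump] - s0) / half))
            r = r * (1.0 - self.stenosis.severity * bump)
        return r

    def default_fiducials(self) -> np.ndarray:
        """A non-coplanar 12-point cage surrounding the vessel."""
        if self.fiducial_layout is not None:
            return np.asarray(self.fiducial_layout, dtype=float)
        ext = self.length
        pts = []
        for z in (-0.1 * ext, 0.55 * ext, 1.1 * ext):
            for x, y in ((-20, -20), (22, -18), (-18, 23), (21, 24)):
                # slight per-point perturbation keeps every subset non-coplanar
                pts.append([x + 0.13 * z, y - 0.07 * z, z + 0.05 * x])
        return np.asarray(pts, dtype=float)


def _analytic_centerline(spec: PhantomSpec, ds: float = 0.2) -> Centerline:
    n = max(int(np.ceil(spec.length / ds)) + 1, 2)
    s = np.linspace(0.0, spec.length, n)
    if spec.centerline_kind == "straight":
        pts = np.column_stack([np.zeros(n), np.zeros(n), s])
        tan = np.tile([0.0, 0.0, 1.0], (n, 1))
        return Centerline(points=pts, arc_length=s, tangents=tan)
    if spec.centerline_kind == "arc":
        rb = spec.bend_radius
        phi = s / rb
        pts = np.column_stack([rb * (1.0 - np.cos(phi)), np.zeros(n), rb * np.sin(phi)])
        tan = np.column_stack([np.sin(phi), np.zeros(n), np.cos(phi)])
        return Centerline(points=pts, arc_length=s, tangents=tan)
    if spec.centerline_kind == "helix":
        a, pitch = spec.bend_radius, spec.helix_pitch
        b = pitch / (2.0 * np.pi)
        c = np.sqrt(a * a + b * b)
        phi = s / c
        pts = np.column_stack([a * np.cos(phi) - a, a * np.sin(phi), b * phi])
        tan = np.column_stack([-a * np.sin(phi) / c, a * np.cos(phi) / c, np.full(n, b / c)])
        return Centerline(points=pts, arc_length=s, tangents=tan)
    # spline through control points, resampled to uniform arc length
    from scipy.interpolate import splev, splprep

    cp = np.asarray(spec.control_points, dtype=float)
    tck, _ = splprep(cp.T, s=0.0, k=min(3, len(cp) - 1))
    u = np.linspace(0.0, 1.0, 20 * n)
    dense = np.column_stack(splev(u, tck))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, arc[-1], n)
    pts = np.column_stack([np.interp(target, arc, dense[:, i]) for i in range(3)])
    return Centerline(points=pts)


@dataclass
class PhantomTruth:
    """Ground-truth products of a phantom: geometry, labels, areas."""

    spec: PhantomSpec
    centerline: Centerline
    label_volume: LabelVolume
    surface: TaggedMesh
    total_area_cm2: float
    false_lumen_area_cm2: float
    per_slice_lumen_area_mm2: np.ndarray
    fiducials_3d: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.false_lumen_area_cm2 > self.total_area_cm2 + 1e-12:
            raise ValueError("false-lumen area cannot exceed total area")
        if self.total_area_cm2 < 0 or self.false_lumen_area_cm2 < 0:
            raise ValueError("areas must be non-negative")


def _dissection_slice_area(spec: PhantomSpec, s: float) -> float:
    d = spec.dissection
    if d is None or not (d.start_mm <= s <= d.end_mm):
        return 0.0
    r = float(spec.radius_at(s)[0])
    theta = np.radians(d.angular_extent_deg)
    ri = r + d.membrane_mm
    ro = ri + d.gap_mm
    return 0.5 * theta * (ro * ro - ri * ri)


def _rasterize_straight_labels(spec: PhantomSpec, voxel_size: np.ndarray) -> LabelVolume:
    d = spec.dissection
    r_max = float(spec.radius_at(np.linspace(0, spec.length, 500)).max())
    extent = r_max + (d.membrane_mm + d.gap_mm if d else 0.0) + 4.0 * voxel_size[0]
    nx = int(np.ceil(2.0 * extent / voxel_size[0]))
    nz = int(np.floor(spec.length / voxel_size[2])) + 1
    half = (nx - 1) / 2.0 * voxel_size[0]
    origin = np.array([-half, -half, 0.0])
    x = origin[0] + np.arange(nx) * voxel_size[0]
    y = origin[1] + np.arange(nx) * voxel_size[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rho = np.hypot(xx, yy)
    ang = np.degrees(np.arctan2(yy, xx))
    arr = np.zeros((nx, nx, nz), dtype=np.uint8)
    for k in range(nz):
        s = k * voxel_size[2]
        r = float(spec.radius_at(s)[0])
        sl = np.where(rho <= r, TRUE_LUMEN, BACKGROUND_U8)
        if d is not None and d.start_mm <= s <= d.end_mm:
            ri, ro = r + d.membrane_mm, r + d.membrane_mm + d.gap_mm
            dang = (ang - d.angle_center_deg + 180.0) % 360.0 - 180.0
            fl = (rho >= ri) & (rho <= ro) & (np.abs(dang) <= d.angular_extent_deg / 2.0)
            sl[fl] = FALSE_LUMEN
        arr[:, :, k] = sl
    return LabelVolume(array=arr, spacing=voxel_size.copy(), origin=origin)


BACKGROUND_U8 = np.uint8(0)


def make_phantom(
    spec: PhantomSpec,
    voxel_size: tuple[float, float, float] = (0.05, 0.05, 0.2),
    centerline_ds: float = 0.2,
) -> PhantomTruth:
    """Build a phantom: analytic centerline, straight label volume, surface.

    The label volume lives in straightened (pullback) space with the
    catheter on the grid axis; the surface is the true-lumen tube swept
    along the anatomical centerline.  Analytic areas (lateral tube area
    plus the false-lumen shell walls) are recorded as ground truth.
    """
    vs = np.asarray(voxel_size, dtype=float)
    cl = _analytic_centerline(spec, ds=centerline_ds)
    label_volume = _rasterize_straight_labels(spec, vs)
    surface = swept_tube_mesh(cl, lambda s: float(spec.radius_at(s)[0]))

    s_dense = np.linspace(0.0, spec.length, 2001)
    r_dense = spec.radius_at(s_dense)
    lateral = float(np.trapezoid(2.0 * np.pi * r_dense, s_dense))
    fl_area = 0.0
    d = spec.dissection
    if d is not None:
        theta = np.radians(d.angular_extent_deg)
        ri = spec.radius + d.membrane_mm
        ro = ri + d.gap_mm
        # false-lumen channel walls: inner + outer arcs and the two radial edges
        perim = theta * (ri + ro) + 2.0 * d.gap_mm
        fl_area = perim * (min(d.end_mm, spec.length) - max(d.start_mm, 0.0))
    per_slice = np.pi * r_dense**2 + np.array([_dissection_slice_area(spec, s) for s in s_dense])
    return PhantomTruth(
        spec=spec,
        centerline=cl,
        label_volume=label_volume,
        surface=surface,
        total_area_cm2=(lateral + fl_area) / 100.0,
        false_lumen_area_cm2=fl_area / 100.0,
        per_slice_lumen_area_mm2=per_slice,
        fiducials_3d=spec.default_fiducials(),
    )


def ideal_projection_geometry(
    azimuth_deg: float,
    elevation_deg: float = 0.0,
    source_distance: float = 1000.0,
    source_detector_distance: float = 1500.0,
    pixel_mm: float = 0.2,
    image_center_px: tuple[float, float] = (512.0, 512.0),
    target: tuple[float, float, float] = (0.0, 0.0, 25.0),
) -> ProjectionGeometry:
    """Pinhole (cone-beam) geometry looking at ``target`` from a given azimuth.

    The source orbits the target in the plane of constant z (elevation
    tilts it out of that plane); magnification is
    ``source_detector_distance / source_distance`` at the target.
    """
    az, el = np.radians(azimuth_deg), np.radians(elevation_deg)
    view_dir = -np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    target = np.asarray(target, dtype=float)
    source = target - view_dir * source_distance
    up_seed = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(up_seed, view_dir)) > 0.99:
        up_seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(view_dir, up_seed)
    u /= np.linalg.norm(u)
    v = np.cross(view_dir, u)
    rot = np.vstack([u, v, view_dir])  # world -> camera
    f_px = source_detector_distance / pixel_mm
    k = np.array([[f_px, 0.0, image_center_px[0]], [0.0, f_px, image_center_px[1]], [0.0, 0.0, 1.0]])
    rt = np.hstack([rot, (-rot @ source)[:, None]])
    return ProjectionGeometry(matrix=k @ rt)


@dataclass
class ProjectedView:
    """Fiducial detections and silhouette boundary traces in one view (px)."""

    fiducials_px: np.ndarray
    boundary_left_px: np.ndarray
    boundary_right_px: np.ndarray


def _silhouette_edges(
    truth: PhantomTruth, geom: ProjectionGeometry
) -> tuple[np.ndarray, np.ndarray]:
    cl = truth.centerline
    cam = geom.camera_center
    rays = cl.points - cam
    rays /= np.linalg.norm(rays, axis=1, keepdims=True)
    e = np.cross(rays, cl.tangents)
    norms = np.linalg.norm(e, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise ValueError("view direction tangent to the vessel: silhouette undefined")
    e /= norms
    r = truth.spec.radius_at(cl.arc_length)[:, None]
    left = geom.project(cl.points + r * e)
    right = geom.project(cl.points - r * e)
    return left, right


def project_phantom(
    truth: PhantomTruth,
    geom_a: ProjectionGeometry,
    geom_b: ProjectionGeometry,
    noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[ProjectedView, ProjectedView]:
    """Render the phantom into two calibrated views.

    Fiducial detections are exact pinhole projections plus isotropic
    Gaussian noise of ``noise_px``; lumen boundaries are the projected
    silhouette edges of the tube.  A view separation below 45 degrees
    warns (acquisition-protocol rule); coincident axes raise.
    """
    check_view_separation(geom_a, geom_b)
    if rng is None:
        rng = np.random.default_rng(truth.spec.seed)
    views = []
    for geom in (geom_a, geom_b):
        fid = geom.project(truth.fiducials_3d)
        if noise_px > 0:
            fid = fid + rng.normal(0.0, noise_px, size=fid.shape)
        left, right = _silhouette_edges(truth, geom)
        views.append(ProjectedView(fiducials_px=fid, boundary_left_px=left, boundary_right_px=right))
    return views[0], views[1]


def render_oct_stack(
    truth: PhantomTruth,
    frame_spacing: float = 0.2,
    pixel_size: float = 0.0102,
    dropout: set[int] | None = None,
    n_contour_points: int = 360,
    rng: np.random.Generator | None = None,
) -> list[ContourSet]:
    """Render the phantom as an OCT-like stack of per-frame contours.

    Frames are cross-sections orthogonal to the centerline at uniform
    arc-length spacing, frame 0 at the distal end (s = 0).  Frames in
    ``dropout`` are marked excluded and carry no contours.  Contour
    points are perturbed radially by the spec's contour noise sigma.
    """
    spec = truth.spec
    if frame_spacing <= 0 or pixel_size <= 0:
        raise ValueError("frame_spacing and pixel_size must be positive")
    if frame_spacing > spec.length:
        raise ValueError("frame_spacing exceeds the phantom length")
    dropout = dropout or set()
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n_frames = int(np.floor(spec.length / frame_spacing)) + 1
    theta = np.linspace(0.0, 2.0 * np.pi, n_contour_points, endpoint=False)
    frames = []
    d = spec.dissection
    for k in range(n_frames):
        if k in dropout:
            frames.append(ContourSet(frame_index=k, quality=FrameQuality.EXCLUDED))
            continue
        s = k * frame_spacing
        r = float(spec.radius_at(s)[0])
        rr = r + (rng.normal(0.0, spec.contour_sigma_mm, n_contour_points) if spec.contour_sigma_mm > 0 else 0.0)
        circle = np.column_stack([rr * np.cos(theta), rr * np.sin(theta)])
        contours: list[tuple[int, np.ndarray]] = [(TRUE_LUMEN, circle)]
        if d is not None and d.start_mm <= s <= d.end_mm:
            half = np.radians(d.angular_extent_deg) / 2.0
            c0 = np.radians(d.angle_center_deg)
            ri, ro = r + d.membrane_mm, r + d.membrane_mm + d.gap_mm
            arc = np.linspace(c0 - half, c0 + half, max(n_contour_points // 4, 16))
            sector = np.vstack(
                [
                    np.column_stack([ri * np.cos(arc), ri * np.sin(arc)]),
                    np.column_stack([ro * np.cos(arc[::-1]), ro * np.sin(arc[::-1])]),
                ]
            )
            contours.append((FALSE_LUMEN, sector))
        frames.append(ContourSet(frame_index=k, contours=contours))
    return frames
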