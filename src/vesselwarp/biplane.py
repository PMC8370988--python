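"""Biplane X-ray calibration, triangulation and centerline extraction.

Two projection views are calibrated from radiopaque fiducials of known
3D position by the direct linear transform (DLT).  Operator-traced
lumen boundary splines in the two views are triangulated into 3D
boundary curves by matched normalized arc length, and the arterial
centerline is taken as the midpoint locus of the two boundaries,
regularized by a smoothing spline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.interpolate import splev, splprep

from .centerline import Centerline, smoothing_spline_centerline

MIN_VIEW_SEPARATION_DEG = 45.0


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class View(str, Enum):
    A = "A"
    B = "B"


@dataclass
class ProjectionGeometry:
    """Calibrated pinhole projection: 3x4 matrix mapping world mm -> image px."""

    matrix: np.ndarray
    reprojection_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 4):
            raise ValueError("projection matrix must be 3x4")
        if np.linalg.matrix_rank(self.matrix) < 3:
            raise ValueError("projection matrix must have rank 3")
        if self.reprojection_rms < 0:
            raise ValueError("reprojection_rms must be non-negative")

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (n, 3) world points to (n, 2) pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]

    @property
    def camera_center(self) -> np.ndarray:
        """Null space of the projection matrix (world mm)."""
        _, _, vt = np.linalg.svd(self.matrix)
        c = vt[-1]
        return c[:3] / c[3]

    @property
    def principal_axis(self) -> np.ndarray:
        """Unit viewing direction (third row of the left 3x3 block, oriented forward)."""
        m = self.matrix[:, :3]
        axis = m[2] * np.sign(np.linalg.det(m))
        return axis / np.linalg.norm(axis)

    def ray(self, pt_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Back-projected ray (origin, unit direction) through a pixel."""
        m = self.matrix[:, :3]
        direction = np.linalg.solve(m, np.array([pt_px[0], pt_px[1], 1.0]))
        direction = direction / np.linalg.norm(direction)
        if np.dot(direction, self.principal_axis) < 0:
            direction = -direction
        return self.camera_center, direction


def view_separation_deg(geom_a: ProjectionGeometry, geom_b: ProjectionGeometry) -> float:
    c = abs(float(np.dot(geom_a.principal_axis, geom_b.principal_axis)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _normalization_2d(pts: np.ndarray) -> np.ndarray:
    centroid = pts.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - centroid, axis=1)), 1e-12)
    t = np.eye(3)
    t[0, 0] = t[1, 1] = scale
    t[:2, 2] = -scale * centroid
    return t


def _normalization_3d(pts: np.ndarray) -> np.ndarray:
    centroid = pts.mean(axis=0)
    scale = np.sqrt(3.0) / max(np.mean(np.linalg.norm(pts - centroid, axis=1)), 1e-12)
    t = np.eye(4)
    t[0, 0] = t[1, 1] = t[2, 2] = scale
    t[:3, 3] = -scale * centroid
    return t


def calibrate_view(fiducials_3d: np.ndarray, detections_2d: np.ndarray) -> ProjectionGeometry:
    """Direct linear transform calibration from >= 6 point correspondences.

    Solves the homogeneous least-squares system for the 3x4 projection
    matrix with Hartley normalization, and reports the RMS reprojection
    error in pixels.  Raises on < 6 correspondences or a (near-)coplanar
    3D fiducial set, both of which leave the DLT underdetermined.
    """
    x3 = np.atleast_2d(np.asarray(fiducials_3d, dtype=float))
    x2 = np.atleast_2d(np.asarray(detections_2d, dtype=float))
    if len(x3) != len(x2):
        raise ValueError("3D/2D correspondence counts differ")
    if len(x3) < 6:
        raise ValueError(f"underdetermined calibration: need >= 6 correspondences, got {len(x3)}")
    centered = x3 - x3.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-6 * sv[0]:
        raise ValueError("underdetermined calibration: fiducials are coplanar")
    t2, t3 = _normalization_2d(x2), _normalization_3d(x3)
    x2n = (np.hstack([x2, np.ones((len(x2), 1))]) @ t2.T)[:, :2]
    x3n = (np.hstack([x3, np.ones((len(x3), 1))]) @ t3.T)[:, :3]
    rows = []
    for (x, y, z), (u, v) in zip(x3n, x2n):
        p = [x, y, z, 1.0]
        rows.append([*p, 0, 0, 0, 0, *(-u * np.asarray(p))])
        rows.append([0, 0, 0, 0, *p, *(-v * np.asarray(p))])
    a = np.asarray(rows)
    _, _, vt = np.linalg.svd(a)
    pn = vt[-1].reshape(3, 4)
    p = np.linalg.inv(t2) @ pn @ t3
    p = p / np.linalg.norm(p)
    geom = ProjectionGeometry(matrix=p)
    residuals = geom.project(x3) - x2
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    geom.reprojection_rms = rms
    return geom


def triangulate_point(
    geom_a: ProjectionGeometry,
    geom_b: ProjectionGeometry,
    pt_a: np.ndarray,
    pt_b: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Midpoint triangulation of one 2D correspondence.

    Returns the 3D point minimizing the distance to both back-projected
    rays (midpoint of the common perpendicular) and the mean
    reprojection residual in px.  Rays closer than 1 degree to parallel
    are rejected as ill-conditioned.
    """
    oa, da = geom_a.ray(np.asarray(pt_a, dtype=float))
    ob, db = geom_b.ray(np.asarray(pt_b, dtype=float))
    cosang = abs(float(np.dot(da, db)))
    if cosang > np.cos(np.radians(1.0)):
        raise ValueError("ill-conditioned triangulation: rays within 1 degree of parallel")
    # least-squares parameters along the two rays
    r = ob - oa
    a11, a12, a22 = np.dot(da, da), -np.dot(da, db), np.dot(db, db)
    b1, b2 = np.dot(da, r), -np.dot(db, r)
    det = a11 * a22 - a12 * a12
    ta = (b1 * a22 - b2 * a12) / det
    tb = (a11 * b2 - a12 * b1) / det
    point = 0.5 * ((oa + ta * da) + (ob + tb * db))
    res_a = np.linalg.norm(geom_a.project(point)[0] - pt_a)
    res_b = np.linalg.norm(geom_b.project(point)[0] - pt_b)
    return point, float(0.5 * (res_a + res_b))


@dataclass
class BoundarySpline:
    """Operator-traced 2D lumen boundary in one view, parameterized on [0, 1]."""

    control_points: np.ndarray
    side: Side
    view: View

    def __post_init__(self) -> None:
        self.control_points = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        if len(self.control_points) < 4:
            raise ValueError("boundary spline needs >= 4 control points")

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Sample the interpolating spline at normalized arc length ``u``."""
        k = min(3, len(self.control_points) - 1)
        tck, _ = splprep(self.control_points.T, s=0.0, k=k)
        return np.column_stack(splev(np.asarray(u, dtype=float), tck))


def triangulate_boundaries(
    splines: list[BoundarySpline],
    geom_a: ProjectionGeometry,
    geom_b: ProjectionGeometry,
    n_samples: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate left/right boundary spline pairs into 3D curves.

    Correspondence across views is by matched normalized arc-length
    parameter; each returned curve has ``n_samples`` points.  Raises if
    the triangulated boundaries cross (inconsistent proximal->distal
    ordering of the input splines).
    """
    if n_samples < 100:
        raise ValueError("boundaries must be sampled at >= 100 parameter values")
    by_key = {(s.view, s.side): s for s in splines}
    needed = [(v, s) for v in (View.A, View.B) for s in (Side.LEFT, Side.RIGHT)]
    missing = [k for k in needed if k not in by_key]
    if missing:
        raise ValueError(f"missing boundary splines: {missing}")
    u = np.linspace(0.0, 1.0, n_samples)
    curves = {}
    for side in (Side.LEFT, Side.RIGHT):
        pa = by_key[(View.A, side)].evaluate(u)
        pb = by_key[(View.B, side)].evaluate(u)
        pts = np.array([triangulate_point(geom_a, geom_b, pa[i], pb[i])[0] for i in range(n_samples)])
        curves[side] = pts
    # the transverse left-to-right separation must not flip between
    # adjacent samples; a sign flip means the triangulated boundaries
    # cross, i.e. the input splines disagree in proximal->distal order
    mid = 0.5 * (curves[Side.LEFT] + curves[Side.RIGHT])
    d = np.gradient(mid, axis=0)
    d /= np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-12)
    w = curves[Side.RIGHT] - curves[Side.LEFT]
    w_perp = w - np.einsum("ij,ij->i", w, d)[:, None] * d
    if np.any(np.einsum("ij,ij->i", w_perp[:-1], w_perp[1:]) < 0):
        raise ValueError("boundary curves cross: inconsistent spline ordering between views")
    return curves[Side.LEFT], curves[Side.RIGHT]


def extract_centerline(
    boundary_a: np.ndarray,
    boundary_b: np.ndarray,
    smoothing: float = 0.1,
    n_samples: int | None = None,
) -> Centerline:
    """Centerline as the smoothed midpoint locus of two 3D boundary curves.

    ``smoothing`` is the residual budget of the smoothing spline (mm^2,
    summed over samples); the default keeps a straight vessel straight
    to well below 0.01 mm while damping triangulation jitter.
    """
    a = np.atleast_2d(np.asarray(boundary_a, dtype=float))
    b = np.atleast_2d(np.asarray(boundary_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("boundary curves must share the same parameter sampling")
    mid = 0.5 * (a + b)
    return smoothing_spline_centerline(mid, smoothing=smoothing, n_samples=n_samples)


def check_view_separation(geom_a: ProjectionGeometry, geom_b: ProjectionGeometry) -> float:
    """Warn when the two view axes are separated by less than 45 degrees."""
    sep = view_separation_deg(geom_a, geom_b)
    if sep < 1.0:
        raise ValueError("degenerate biplane geometry: view axes nearly coincident")
    if sep < MIN_VIEW_SEPARATION_DEG:
        warnings.warn(
            f"view separation {sep:.1f} deg below the >45 deg acquisition rule",
            stacklevel=2,
        )
    return sep
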