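"""Arc-length parameterized 3D centerlines with rotation-minimizing frames.

The centerline is the geometric backbone shared by the biplane
reconstruction and the OCT warping stages: an ordered polyline in mm,
its cumulative arc length, and a per-sample orthonormal triad
(tangent, normal, binormal).  Frames are transported by the
double-reflection method so that they are rotation minimizing: a
straight segment carries a constant frame and no spurious twist
accumulates along near-straight arteries, where Frenet frames would be
undefined at inflection points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splprep


def _finite_difference_tangents(points: np.ndarray) -> np.ndarray:
    """Central-difference unit tangents (one-sided at the ends)."""
    tangents = np.empty_like(points)
    tangents[1:-1] = points[2:] - points[:-2]
    tangents[0] = points[1] - points[0]
    tangents[-1] = points[-1] - points[-2]
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("duplicate consecutive centerline points")
    return tangents / norms


def rotation_minimizing_frames(
    points: np.ndarray,
    tangents: np.ndarray,
    normal0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Transport an initial normal along the curve by double reflection.

    Returns (normals, binormals), each of shape (n, 3), orthonormal to
    the supplied tangents.
    """
    n = len(points)
    normals = np.empty((n, 3))
    if normal0 is None:
        # any vector least aligned with the first tangent
        seed = np.eye(3)[np.argmin(np.abs(tangents[0]))]
        normal0 = seed - np.dot(seed, tangents[0]) * tangents[0]
    normal0 = np.asarray(normal0, dtype=float)
    normal0 = normal0 - np.dot(normal0, tangents[0]) * tangents[0]
    nrm = np.linalg.norm(normal0)
    if nrm < 1e-12:
        raise ValueError("initial normal is parallel to the first tangent")
    normals[0] = normal0 / nrm
    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-24:
            normals[i + 1] = normals[i]
            continue
        # reflect frame i across the bisecting plane of the segment
        r_l = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        t_l = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        # second reflection maps the reflected tangent onto tangent i+1
        v2 = tangents[i + 1] - t_l
        c2 = np.dot(v2, v2)
        if c2 < 1e-24:
            normals[i + 1] = r_l
        else:
            normals[i + 1] = r_l - (2.0 / c2) * np.dot(v2, r_l) * v2
        # re-orthonormalize against drift
        normals[i + 1] -= np.dot(normals[i + 1], tangents[i + 1]) * tangents[i + 1]
        normals[i + 1] /= np.linalg.norm(normals[i + 1])
    binormals = np.cross(tangents, normals)
    return normals, binormals


@dataclass
class Centerline:
    """Ordered 3D polyline with arc length and orthonormal frames.

    Attributes
    ----------
    points : (n, 3) float array, mm
    arc_length : (n,) cumulative arc length, mm, strictly increasing
    tangents, normals, binormals : (n, 3) orthonormal triads
    """

    points: np.ndarray
    arc_length: np.ndarray = field(default=None)  # type: ignore[assignment]
    tangents: np.ndarray = field(default=None)  # type: ignore[assignment]
    normals: np.ndarray = field(default=None)  # type: ignore[assignment]
    binormals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least two points")
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(seg <= 0):
                raise ValueError("arc length must be strictly increasing")
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc length must be strictly increasing")
        if self.tangents is None:
            self.tangents = _finite_difference_tangents(self.points)
        else:
            self.tangents = np.asarray(self.tangents, dtype=float)
            norms = np.linalg.norm(self.tangents, axis=1, keepdims=True)
            self.tangents = self.tangents / norms
        if self.normals is None or self.binormals is None:
            self.normals, self.binormals = rotation_minimizing_frames(
                self.points, self.tangents
            )

    @property
    def length(self) -> float:
        return float(self.arc_length[-1] - self.arc_length[0])

    def frames(self) -> np.ndarray:
        """(n, 3, 3) rotation matrices with columns (normal, binormal, tangent)."""
        return np.stack([self.normals, self.binormals, self.tangents], axis=2)

    def interpolate(self, s: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of position at arc length(s) ``s`` (mm)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.column_stack(
            [np.interp(s, self.arc_length, self.points[:, i]) for i in range(3)]
        )
        return out

    def interpolate_frame(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Tangent/normal/binormal at arc length ``s`` from the nearest sample."""
        i = int(np.argmin(np.abs(self.arc_length - s)))
        return self.tangents[i], self.normals[i], self.binormals[i]

    def resample(self, n: int) -> "Centerline":
        """Resample at ``n`` uniformly spaced arc-length values."""
        s = np.linspace(self.arc_length[0], self.arc_length[-1], n)
        return Centerline(points=self.interpolate(s))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Centerline":
        pts = self.points @ rotation.T + translation
        return Centerline(
            points=pts,
            arc_length=self.arc_length.copy(),
            tangents=self.tangents @ rotation.T,
            normals=self.normals @ rotation.T,
            binormals=self.binormals @ rotation.T,
        )


def smoothing_spline_centerline(
    points: np.ndarray, smoothing: float = 0.0, n_samples: int | None = None
) -> Centerline:
    """Fit a smoothing spline through noisy 3D samples and resample it.

    ``smoothing`` is the scipy ``splprep`` residual budget (mm^2 summed
    over samples); 0 interpolates.  The default sample count matches
    the input.
    """
    points = np.asarray(points, dtype=float)
    if n_samples is None:
        n_samples = len(points)
    # splprep requires strictly increasing parameter; use chord length
    tck, _ = splprep(points.T, s=smoothing, k=min(3, len(points) - 1))
    u = np.linspace(0.0, 1.0, n_samples)
    fitted = np.column_stack(splev(u, tck))
    return Centerline(points=fitted)


def hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two 3D point sets (mm)."""
    from scipy.spatial import cKDTree

    ta, tb = cKDTree(a), cKDTree(b)
    d_ab = ta.query(b)[0].max()
    d_ba = tb.query(a)[0].max()
    return float(max(d_ab, d_ba))


def directed_max_distance(a: np.ndarray, b: np.ndarray) -> float:
    """max over points of ``a`` of the distance to the nearest point of ``b``."""
    from scipy.spatial import cKDTree

    return float(cKDTree(b).query(a)[0].max())
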