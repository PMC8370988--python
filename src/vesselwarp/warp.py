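"""Warping the straightened OCT lumen onto the X-ray centerline.

The straight label volume is mapped to anatomical space by a per-slice
rigid motion: each pullback slice is translated to its corresponding
arc-length position on the X-ray centerline and rotated so its plane is
orthogonal to the local tangent, with in-plane orientation carried by
rotation-minimizing frame transport (no twist accumulation).  The
resulting forward (source -> target) displacement field is inverted by
fixed-point iteration into a dense inverse field, which pulls the
categorical labels back from target voxels to source positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import binary_dilation, distance_transform_edt, map_coordinates

from .centerline import Centerline
from .octstack import LabelVolume


@dataclass
class RigidTransform:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class Alignment:
    """Rigid transform plus arc-length correspondence s_target(s_source)."""

    rigid: RigidTransform
    arc_map: Callable[[np.ndarray], np.ndarray]
    landmarks: np.ndarray  # (n, 2) (s_source, s_target) mm


def centerline_from_label(
    volume: LabelVolume,
    end_trim_fraction: float = 0.95,
    end_trim_window: int = 20,
    return_indices: bool = False,
) -> Centerline | tuple[Centerline, np.ndarray]:
    """Per-slice lumen centroid centerline of a label volume.

    Each slice along the third grid axis contributes the centroid of its
    lumen voxels (true and false lumen).  Terminal slices whose lumen
    voxel count falls below ``end_trim_fraction`` of the median count of
    the next ``end_trim_window`` slices inward are trimmed: on warped
    volumes these are partial oblique cuts of the vessel ends whose
    centroids sit off-axis.  An empty slice strictly inside the
    populated range raises.
    """
    mask = volume.array > 0
    counts = mask.sum(axis=(0, 1))
    populated = np.nonzero(counts)[0]
    if len(populated) < 2:
        raise ValueError("fewer than two populated slices")
    interior = np.arange(populated[0], populated[-1] + 1)
    if np.any(counts[interior] == 0):
        empty = interior[counts[interior] == 0]
        raise ValueError(f"empty slices inside the ROI: {empty.tolist()}")
    keep = list(populated)
    for flip in (False, True):
        if flip:
            keep.reverse()
        while len(keep) > 2:
            look = [counts[k] for k in keep[1 : 1 + end_trim_window]]
            if counts[keep[0]] < end_trim_fraction * np.median(look):
                keep.pop(0)
            else:
                break
    keep.sort()
    if len(keep) < 2:
        raise ValueError("too few full-lumen slices after end trimming")
    pts = []
    for k in keep:
        ii, jj = np.nonzero(mask[:, :, k])
        center_idx = np.array([ii.mean(), jj.mean(), float(k)])
        pts.append(volume.origin + center_idx * volume.spacing)
    cl = Centerline(points=np.asarray(pts))
    if return_indices:
        return cl, np.asarray(keep, dtype=int)
    return cl


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=r, translation=tc - r @ sc)


def align_centerlines(
    oct_cl: Centerline,
    xray_cl: Centerline,
    landmark_pairs: list[tuple[float, float]] | None = None,
    n_samples: int = 200,
) -> Alignment:
    """Rigidly align the OCT centerline to the X-ray centerline.

    The arc-length correspondence is piecewise linear through the
    landmark pairs (default: matched endpoints, i.e. normalized arc
    length); the rigid transform is the least-squares (Procrustes, no
    scaling) fit over corresponding samples.
    """
    if landmark_pairs is None:
        landmark_pairs = [
            (float(oct_cl.arc_length[0]), float(xray_cl.arc_length[0])),
            (float(oct_cl.arc_length[-1]), float(xray_cl.arc_length[-1])),
        ]
    lm = np.asarray(landmark_pairs, dtype=float)
    if len(lm) < 2:
        raise ValueError("need at least two landmark pairs")
    if np.any(np.diff(lm[:, 0]) <= 0) or np.any(np.diff(lm[:, 1]) <= 0):
        raise ValueError("landmark arc lengths must be strictly increasing in both centerlines")

    def arc_map(s: np.ndarray | float) -> np.ndarray:
        return np.interp(np.atleast_1d(np.asarray(s, dtype=float)), lm[:, 0], lm[:, 1])

    s_src = np.linspace(lm[0, 0], lm[-1, 0], n_samples)
    src = oct_cl.interpolate(s_src)
    tgt = xray_cl.interpolate(arc_map(s_src))
    return Alignment(rigid=_kabsch(src, tgt), arc_map=arc_map, landmarks=lm)


@dataclass
class SliceMap:
    """Per-slice rigid poses placing pullback slices on the X-ray centerline."""

    source_z_index: np.ndarray  # (n,)
    target_s: np.ndarray  # (n,) mm, monotone in source index
    rotations: np.ndarray  # (n, 3, 3)
    source_points: np.ndarray  # (n, 3) source slice anchor points (mm)
    target_points: np.ndarray  # (n, 3)
    target_tangents: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.target_s) < 0):
            raise ValueError("target arc lengths must be monotone in source index")
        det = np.linalg.det(self.rotations)
        if not np.allclose(det, 1.0, atol=1e-6):
            raise ValueError("slice rotations must be proper (det=+1)")
        if self.target_tangents is None:
            self.target_tangents = self.rotations[:, :, 2].copy()

    def pose_of(self, k_index: int) -> int:
        pos = int(np.searchsorted(self.source_z_index, k_index))
        if pos >= len(self.source_z_index) or self.source_z_index[pos] != k_index:
            raise KeyError(f"no pose for source slice {k_index}")
        return pos

    def apply(self, k_index: int, points: np.ndarray) -> np.ndarray:
        """Map source-space points attached to slice ``k_index`` to target space."""
        i = self.pose_of(k_index)
        r, c_src, c_tgt = self.rotations[i], self.source_points[i], self.target_points[i]
        return (np.atleast_2d(points) - c_src) @ r.T + c_tgt


def build_slice_map(
    oct_cl: Centerline,
    xray_cl: Centerline,
    alignment: Alignment,
    roll_deg: float = 0.0,
    source_z_index: np.ndarray | None = None,
    anchor_smooth_mm: float = 2.0,
) -> SliceMap:
    """Rigid pose per source slice: translate to the corresponding
    arc-length point and rotate the slice plane onto the X-ray frame.

    Source slices of a straightened pullback volume are orthogonal to
    the grid axis by construction, so the source frame is the canonical
    grid triad (ex, ey, ez); the per-slice lumen-centroid centerline
    supplies the arc-length parameterization and the in-plane anchor
    points that are carried onto the X-ray centerline.  Each slice is
    rotated so its plane normal equals the X-ray tangent at the mapped
    arc length, with in-plane orientation following the target's
    rotation-minimizing frames (no twist accumulation).  The in-plane
    roll of the target frames is fixed at the proximal slice so that
    its pose is rotation minimal with respect to the source grid axes;
    ``roll_deg`` adds a global roll on top (landmark-based roll
    registration hook).  ``source_z_index`` names the volume slice of
    each centerline sample (default: consecutive from 0, the untrimmed
    case).  The in-plane anchor points (per-slice lumen centroids) are
    smoothed over ``anchor_smooth_mm`` of arc length so abrupt centroid
    jumps — e.g. at the onset of a dissection false lumen — do not
    shear adjacent slices.
    """
    n = len(oct_cl.points)
    if source_z_index is None:
        source_z_index = np.arange(n)
    source_z_index = np.asarray(source_z_index, dtype=int)
    if len(source_z_index) != n:
        raise ValueError("source_z_index must align with the centerline samples")

    anchors = oct_cl.points.copy()
    if anchor_smooth_mm > 0 and n > 2:
        from scipy.ndimage import gaussian_filter1d

        ds = float(np.mean(np.diff(oct_cl.arc_length)))
        sigma = anchor_smooth_mm / max(ds, 1e-9)
        anchors[:, 0] = gaussian_filter1d(anchors[:, 0], sigma, mode="nearest")
        anchors[:, 1] = gaussian_filter1d(anchors[:, 1], sigma, mode="nearest")
    # correspondence uses the smoothed anchor curve's arc length: the raw
    # centroid polyline inherits lateral jumps (dissection onsets) that
    # would advance the mapped position discontinuously between slices
    seg = np.linalg.norm(np.diff(anchors, axis=0), axis=1)
    s_src = oct_cl.arc_length[0] + np.concatenate([[0.0], np.cumsum(seg)])
    s_tgt = alignment.arc_map(s_src)
    lo, hi = xray_cl.arc_length[0], xray_cl.arc_length[-1]
    if np.any(s_tgt < lo - 1e-6) or np.any(s_tgt > hi + 1e-6):
        raise ValueError("correspondence maps outside the X-ray centerline range")

    # proximal-slice roll anchoring: roll all target frames so the first
    # slice's in-plane axes are as close as possible to the grid axes
    t0, n0, b0 = xray_cl.tangents[0], xray_cl.normals[0], xray_cl.binormals[0]
    ex = np.array([1.0, 0.0, 0.0])
    desired = ex - np.dot(ex, t0) * t0
    if np.linalg.norm(desired) < 1e-9:
        desired = np.array([0.0, 1.0, 0.0]) - np.dot([0.0, 1.0, 0.0], t0) * t0
    desired /= np.linalg.norm(desired)
    roll = np.arctan2(np.dot(desired, b0), np.dot(desired, n0)) + np.radians(roll_deg)
    cr, sr = np.cos(roll), np.sin(roll)

    rotations = np.empty((n, 3, 3))
    target_points = np.empty((n, 3))
    target_tangents = np.empty((n, 3))
    for i in range(n):
        # nearest-sample frame of the target at the mapped arc length
        j = int(np.argmin(np.abs(xray_cl.arc_length - s_tgt[i])))
        t_t, n_t, b_t = xray_cl.tangents[j], xray_cl.normals[j], xray_cl.binormals[j]
        n_t, b_t = cr * n_t + sr * b_t, -sr * n_t + cr * b_t
        # source frame is the grid triad, so the rotation is the target frame
        rotations[i] = np.stack([n_t, b_t, t_t], axis=1)
        target_points[i] = xray_cl.interpolate(s_tgt[i])[0]
        target_tangents[i] = t_t
    return SliceMap(
        source_z_index=source_z_index,
        target_s=s_tgt,
        rotations=rotations,
        source_points=anchors,
        target_points=target_points,
        target_tangents=target_tangents,
    )


@dataclass
class Grid:
    """Regular voxel grid: world = origin + index * spacing."""

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple[int, int, int]

    def axes(self) -> list[np.ndarray]:
        return [self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)]


@dataclass
class DisplacementField:
    """Dense per-voxel displacement vectors (mm) on a regular grid.

    ``direction`` is ``forward`` (source -> target) or ``inverse``
    (target -> source); ``mask`` marks voxels where the field is
    defined (the lumen support band).
    """

    grid: Grid
    vectors: np.ndarray  # (nx, ny, nz, 3), mm
    direction: str
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    dense: bool = False  # vectors valid on the whole grid, not only the mask
    residual: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "inverse"):
            raise ValueError("direction must be 'forward' or 'inverse'")
        if not np.all(np.isfinite(self.vectors[self.mask if self.mask is not None else ...])):
            raise ValueError("displacement vectors must be finite")


def _curvature_check(slice_map: SliceMap, volume: LabelVolume) -> None:
    """Reject bends tighter than 5x the lumen radius (self-intersecting slabs)."""
    ds = np.diff(slice_map.target_s)
    t = slice_map.target_tangents
    dots = np.clip(np.einsum("ij,ij->i", t[:-1], t[1:]), -1.0, 1.0)
    dphi = np.arccos(dots)
    with np.errstate(divide="ignore"):
        curv = np.where(ds > 1e-6, dphi / np.maximum(ds, 1e-12), 0.0)
    kappa = curv.max() if len(curv) else 0.0
    if kappa <= 1e-12:
        return
    mask = volume.array > 0
    ii, jj, _ = np.nonzero(mask)
    if len(ii) == 0:
        return
    x = volume.origin[0] + ii * volume.spacing[0]
    y = volume.origin[1] + jj * volume.spacing[1]
    r_max = float(np.hypot(x, y).max())
    if 1.0 / kappa < 5.0 * r_max:
        raise ValueError(
            f"target bend radius {1.0 / kappa:.1f} mm below 5x lumen radius "
            f"({r_max:.1f} mm): slice slabs would self-intersect"
        )


def forward_field(
    volume: LabelVolume,
    slice_map: SliceMap,
    band_voxels: int = 3,
) -> DisplacementField:
    """Forward displacement field of the straight-to-anatomical mapping.

    The displacement of a voxel center in slice k is its per-slice rigid
    pose image minus its source position.  Because each slice's rigid
    transform is globally defined, the field is evaluated densely on
    every covered slice (slices without a pose — trimmed ends — inherit
    the nearest covered slice's transform), which keeps it smooth
    across label discontinuities such as dissection onsets.  ``mask``
    marks the lumen dilated by ``band_voxels``: the support that the
    inversion and warping stages consider meaningful.
    """
    _curvature_check(slice_map, volume)
    mask = binary_dilation(volume.array > 0, iterations=band_voxels)
    nx, ny, nz = volume.shape
    if np.max(slice_map.source_z_index) >= nz:
        raise ValueError("slice map references slices beyond the volume")
    pose_of_slice = np.full(nz, -1, dtype=int)
    pose_of_slice[slice_map.source_z_index] = np.arange(len(slice_map.source_z_index))
    # trimmed slices inherit the nearest covered pose
    covered_idx = np.nonzero(pose_of_slice >= 0)[0]
    for k in range(nz):
        if pose_of_slice[k] < 0:
            pose_of_slice[k] = pose_of_slice[covered_idx[np.argmin(np.abs(covered_idx - k))]]
            mask[:, :, k] = False
    vectors = np.empty((nx, ny, nz, 3), dtype=np.float64)
    x = volume.origin[0] + np.arange(nx) * volume.spacing[0]
    y = volume.origin[1] + np.arange(ny) * volume.spacing[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    flat_xy = np.column_stack([xx.ravel(), yy.ravel()])
    for k in range(nz):
        i = int(pose_of_slice[k])
        z = volume.origin[2] + k * volume.spacing[2]
        pts = np.column_stack([flat_xy, np.full(len(flat_xy), z)])
        r, c_src, c_tgt = slice_map.rotations[i], slice_map.source_points[i], slice_map.target_points[i]
        warped = (pts - c_src) @ r.T + c_tgt
        vectors[:, :, k] = (warped - pts).reshape(nx, ny, 3)
    grid = Grid(origin=volume.origin.copy(), spacing=volume.spacing.copy(), shape=volume.shape)
    return DisplacementField(grid=grid, vectors=vectors, direction="forward", mask=mask, dense=True)


def _nearest_extended(vectors: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend field values from the band to the full grid by nearest voxel."""
    if mask.all():
        return vectors
    idx = distance_transform_edt(~mask, return_distances=False, return_indices=True)
    return vectors[idx[0], idx[1], idx[2]]


def default_target_grid(
    forward: DisplacementField,
    spacing: np.ndarray | float | None = None,
    pad_voxels: int = 2,
) -> Grid:
    """Axis-aligned grid covering the forward-mapped band, padded 2 voxels."""
    sp = forward.grid.spacing if spacing is None else np.broadcast_to(np.asarray(spacing, float), (3,)).copy()
    m = forward.mask
    ii, jj, kk = np.nonzero(m)
    src = forward.grid.origin + np.column_stack([ii, jj, kk]) * forward.grid.spacing
    tgt = src + forward.vectors[m]
    lo = tgt.min(axis=0) - pad_voxels * sp
    hi = tgt.max(axis=0) + pad_voxels * sp
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / sp[a])) + 1 for a in range(3))
    return Grid(origin=lo, spacing=sp, shape=shape)  # type: ignore[arg-type]


def invert_field(
    forward: DisplacementField,
    target_grid: Grid | None = None,
    tol_voxel: float = 0.01,
    max_iter: int = 50,
    band_voxels: int = 3,
) -> DisplacementField:
    """Dense inverse displacement field by fixed-point iteration.

    Iterates ``v <- -u(y + v(y))`` on target voxels near the mapped
    lumen until the largest update falls below ``tol_voxel`` voxels
    (or raises after ``max_iter`` iterations with a residual summary).
    The returned field's ``residual`` records the composition error
    ``|u(y + v(y)) + v(y)|`` over the support.
    """
    if forward.direction != "forward":
        raise ValueError("invert_field expects a forward field")
    if target_grid is None:
        target_grid = default_target_grid(forward)
    u_ext = forward.vectors if forward.dense else _nearest_extended(forward.vectors, forward.mask)
    _interp = RegularGridInterpolator(
        forward.grid.axes(), u_ext, method="linear", bounds_error=False, fill_value=None
    )
    axes = forward.grid.axes()
    lo_b = np.array([a[0] for a in axes])
    hi_b = np.array([a[-1] for a in axes])

    def interp(pts: np.ndarray) -> np.ndarray:
        # clamp to the source grid so the extension stays bounded
        return _interp(np.clip(pts, lo_b, hi_b))
    # target support: splat forward-mapped band voxels, then dilate
    m = forward.mask
    ii, jj, kk = np.nonzero(m)
    src = forward.grid.origin + np.column_stack([ii, jj, kk]) * forward.grid.spacing
    tgt = src + forward.vectors[m]
    tgt_idx = np.round((tgt - target_grid.origin) / target_grid.spacing).astype(int)
    shape = target_grid.shape
    inside = np.all((tgt_idx >= 0) & (tgt_idx < np.asarray(shape)), axis=1)
    core = np.zeros(shape, dtype=bool)
    core[tgt_idx[inside, 0], tgt_idx[inside, 1], tgt_idx[inside, 2]] = True
    support = binary_dilation(core, iterations=band_voxels)
    si, sj, sk = np.nonzero(support)
    on_core = core[si, sj, sk]
    y = target_grid.origin + np.column_stack([si, sj, sk]) * target_grid.spacing
    # initial guess: splat the negated forward vectors at their target voxels
    # (averaged where several land together), nearest-extended over the band;
    # the fixed point then only refines by sub-voxel corrections
    v0_sum = np.zeros((*shape, 3))
    v0_cnt = np.zeros(shape)
    np.add.at(v0_sum, (tgt_idx[inside, 0], tgt_idx[inside, 1], tgt_idx[inside, 2]), -forward.vectors[m][inside])
    np.add.at(v0_cnt, (tgt_idx[inside, 0], tgt_idx[inside, 1], tgt_idx[inside, 2]), 1.0)
    v0 = np.where(v0_cnt[..., None] > 0, v0_sum / np.maximum(v0_cnt, 1.0)[..., None], 0.0)
    v0 = _nearest_extended(v0, v0_cnt > 0)
    v = v0[si, sj, sk]
    tol = tol_voxel * float(np.min(target_grid.spacing))
    converged = False
    # convergence is judged on the core (voxels that are images of lumen-band
    # voxels); the dilated fringe only buffers interpolation at the boundary,
    # where the nearest-extended forward field is not contractive
    for _ in range(max_iter):
        v_new = -interp(y + v)
        delta = np.abs((v_new - v)[on_core]).max() if on_core.any() else 0.0
        v = v_new
        if delta < tol:
            converged = True
            break
    residual_vec = interp(y + v) + v
    res_mag = np.linalg.norm(residual_vec[on_core], axis=1) if on_core.any() else np.zeros(0)
    summary = {
        "max_mm": float(res_mag.max()) if len(res_mag) else 0.0,
        "mean_mm": float(res_mag.mean()) if len(res_mag) else 0.0,
        "n_support": int(len(res_mag)),
        "n_clipped": int(np.count_nonzero(~inside)),
    }
    if not converged:
        raise RuntimeError(f"inverse field did not converge in {max_iter} iterations: {summary}")
    vectors = np.zeros((*shape, 3), dtype=np.float64)
    vectors[si, sj, sk] = v
    return DisplacementField(
        grid=target_grid, vectors=vectors, direction="inverse", mask=support, residual=summary
    )


def warp_labels(
    volume: LabelVolume,
    inverse: DisplacementField,
    target_grid: Grid | None = None,
) -> LabelVolume:
    """Pull labels to target space through the inverse field.

    Each target voxel takes the source label at ``y + v(y)`` by
    nearest-neighbor lookup.  Raises if forward-mapped lumen voxels
    would be clipped by the target grid.
    """
    if inverse.direction != "inverse":
        raise ValueError("warp_labels expects an inverse field")
    if inverse.residual.get("n_clipped", 0) > 0:
        raise ValueError(
            f"target grid clips {inverse.residual['n_clipped']} mapped lumen-band voxels"
        )
    grid = inverse.grid if target_grid is None else target_grid
    if grid is not inverse.grid and (
        not np.allclose(grid.origin, inverse.grid.origin)
        or not np.allclose(grid.spacing, inverse.grid.spacing)
        or grid.shape != inverse.grid.shape
    ):
        raise ValueError("target grid must match the inverse field grid")
    si, sj, sk = np.nonzero(inverse.mask)
    y = grid.origin + np.column_stack([si, sj, sk]) * grid.spacing
    src = y + inverse.vectors[si, sj, sk]
    src_idx = (src - volume.origin) / volume.spacing
    labels = map_coordinates(volume.array, src_idx.T, order=0, mode="constant", cval=0)
    arr = np.zeros(grid.shape, dtype=np.uint8)
    arr[si, sj, sk] = labels
    return LabelVolume(array=arr, spacing=grid.spacing.copy(), origin=grid.origin.copy())


def measure_cross_section_area(
    volume: LabelVolume,
    centerline: Centerline,
    s: float,
    labels: tuple[int, ...] = (1, 2),
    extent: float = 5.0,
    pixel: float = 0.05,
) -> float:
    """Lumen area (mm^2) of the plane orthogonal to the centerline at ``s``.

    Samples the label volume on a fine in-plane grid spanned by the
    centerline frame at ``s`` (nearest-neighbor lookup) and sums the
    covered pixel area; used for slice-area conservation checks on
    warped volumes.
    """
    t, nvec, bvec = centerline.interpolate_frame(s)
    c = centerline.interpolate(s)[0]
    coords = np.arange(-extent, extent + pixel / 2, pixel)
    aa, bb = np.meshgrid(coords, coords, indexing="ij")
    pts = c + aa[..., None] * nvec + bb[..., None] * bvec
    idx = (pts.reshape(-1, 3) - volume.origin) / volume.spacing
    vals = map_coordinates(volume.array, idx.T, order=0, mode="constant", cval=0)
    return float(np.isin(vals, labels).sum() * pixel * pixel)
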