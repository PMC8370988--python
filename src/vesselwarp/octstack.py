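"""OCT contour stacks to straightened label volumes.

Per-frame lumen contours (true and false lumen, drawn on cross-sections
orthogonal to the pullback axis) are rasterized into a 3-label voxel
grid: 0 background, 1 true lumen, 2 false lumen.  Frames excluded for
quality are left empty and later filled by shape-aware interpolation;
the volume is finally resampled to an isotropic grid for warping and
surface extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt
from skimage.draw import polygon2mask

BACKGROUND = 0
TRUE_LUMEN = 1
FALSE_LUMEN = 2


class FrameQuality(str, Enum):
    OK = "ok"
    EXCLUDED = "excluded"


@dataclass
class ContourSet:
    """Lumen contours of one pullback frame.

    ``contours`` is a list of (region_tag, points) pairs, with points an
    (n, 2) array in mm, in-plane, ordered along the closed curve (the
    closing segment from last to first point is implicit).  Excluded
    frames carry no contours.
    """

    frame_index: int
    contours: list[tuple[int, np.ndarray]] = field(default_factory=list)
    quality: FrameQuality = FrameQuality.OK

    def __post_init__(self) -> None:
        if self.quality == FrameQuality.EXCLUDED and self.contours:
            raise ValueError("excluded frames must not carry contours")
        for tag, pts in self.contours:
            if tag not in (TRUE_LUMEN, FALSE_LUMEN):
                raise ValueError(f"unknown region tag {tag}")


@dataclass
class LabelVolume:
    """3-label voxel grid with physical spacing and origin.

    ``array`` is indexed ``[ix, iy, iz]``; the world position of voxel
    center (i, j, k) is ``origin + (i, j, k) * spacing`` (mm).  Slices
    along the third axis are the pullback frames (straight space) or
    axial cuts (warped space).
    """

    array: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.array.ndim != 3:
            raise ValueError("label array must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        labels = np.unique(self.array)
        if not np.all(np.isin(labels, [BACKGROUND, TRUE_LUMEN, FALSE_LUMEN])):
            raise ValueError(f"labels outside {{0,1,2}}: {labels}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world points (mm)."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.atleast_2d(indices) * self.spacing

    def labeled_volume_mm3(self, labels: tuple[int, ...] = (TRUE_LUMEN, FALSE_LUMEN)) -> float:
        return float(np.isin(self.array, labels).sum() * self.voxel_volume)

    def slice_area_mm2(self, k: int, labels: tuple[int, ...] = (TRUE_LUMEN, FALSE_LUMEN)) -> float:
        return float(
            np.isin(self.array[:, :, k], labels).sum() * self.spacing[0] * self.spacing[1]
        )


def _rasterize_contour(
    points_mm: np.ndarray,
    origin_xy: np.ndarray,
    pixel_size: float,
    shape_xy: tuple[int, int],
    frame_index: int,
) -> np.ndarray:
    pts = np.asarray(points_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError(f"open or degenerate contour on frame {frame_index}")
    # a genuinely open polyline: closing gap much longer than typical edge
    edges = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    gap = np.linalg.norm(pts[0] - pts[-1])
    if gap > max(10.0 * np.median(edges), 0.5):
        raise ValueError(f"open contour on frame {frame_index} (closing gap {gap:.3f} mm)")
    idx = (pts - origin_xy) / pixel_size  # (x_idx, y_idx), axis 0 = x
    return polygon2mask(shape_xy, idx)


def contours_to_labels(
    frames: list[ContourSet],
    pixel_size: float,
    frame_spacing: float,
    grid_extent: int,
) -> LabelVolume:
    """Rasterize per-frame contours into a straightened label volume.

    The in-plane grid is ``grid_extent`` x ``grid_extent`` voxels of
    ``pixel_size`` mm centered on the catheter axis (x = y = 0); frame k
    sits at z = k * ``frame_spacing``.  False-lumen contours are
    rasterized after the true lumen so that the false-lumen label wins
    on overlap.  Excluded frames are left empty for interpolation.
    """
    if pixel_size <= 0 or frame_spacing <= 0:
        raise ValueError("pixel_size and frame_spacing must be positive")
    if not frames:
        raise ValueError("no frames supplied")
    order = np.argsort([f.frame_index for f in frames])
    frames = [frames[i] for i in order]
    n_z = frames[-1].frame_index + 1
    shape_xy = (grid_extent, grid_extent)
    half = (grid_extent - 1) / 2.0 * pixel_size
    origin = np.array([-half, -half, 0.0])
    array = np.zeros((grid_extent, grid_extent, n_z), dtype=np.uint8)
    for f in frames:
        if f.quality == FrameQuality.EXCLUDED:
            continue
        sl = np.zeros(shape_xy, dtype=np.uint8)
        for tag in (TRUE_LUMEN, FALSE_LUMEN):  # false lumen last: wins on overlap
            for ctag, pts in f.contours:
                if ctag != tag:
                    continue
                mask = _rasterize_contour(pts, origin[:2], pixel_size, shape_xy, f.frame_index)
                sl[mask] = tag
        array[:, :, f.frame_index] = sl
    return LabelVolume(array=array, spacing=np.array([pixel_size, pixel_size, frame_spacing]), origin=origin)


def _signed_distance(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Signed distance, negative inside ``mask`` (mm)."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    inside = distance_transform_edt(mask, sampling=spacing)
    outside = distance_transform_edt(~mask, sampling=spacing)
    return outside - inside


def interpolate_missing(
    volume: LabelVolume,
    annotated: set[int] | list[int],
    max_gap: int = 10,
) -> LabelVolume:
    """Fill un-annotated slices by per-label signed-distance interpolation.

    For each missing slice between two annotated neighbors, the signed
    distance maps of each label are linearly blended by slice position
    and thresholded at zero; slices beyond the first/last annotated
    slice are nearest-neighbor copies.  Gaps larger than ``max_gap``
    missing slices raise.
    """
    annotated = sorted(set(int(a) for a in annotated))
    if len(annotated) < 2:
        raise ValueError("need at least two annotated slices")
    n_z = volume.shape[2]
    gaps = np.diff(annotated) - 1
    if np.any(gaps > max_gap):
        bad = [
            (annotated[i], annotated[i + 1])
            for i in range(len(gaps))
            if gaps[i] > max_gap
        ]
        raise ValueError(f"annotation gaps exceed {max_gap} slices: {bad}")
    out = volume.array.copy()
    sp2 = volume.spacing[:2]
    sdf_cache: dict[tuple[int, int], np.ndarray] = {}

    def sdf(k: int, label: int) -> np.ndarray:
        key = (k, label)
        if key not in sdf_cache:
            sdf_cache[key] = _signed_distance(volume.array[:, :, k] == label, sp2)
        return sdf_cache[key]

    ann = np.asarray(annotated)
    for k in range(n_z):
        if k in annotated:
            continue
        lo = ann[ann < k]
        hi = ann[ann > k]
        if len(lo) == 0:  # extrapolate: copy nearest
            out[:, :, k] = volume.array[:, :, hi[0]]
            continue
        if len(hi) == 0:
            out[:, :, k] = volume.array[:, :, lo[-1]]
            continue
        k0, k1 = int(lo[-1]), int(hi[0])
        w = (k - k0) / (k1 - k0)
        sl = np.zeros(volume.shape[:2], dtype=np.uint8)
        for label in (TRUE_LUMEN, FALSE_LUMEN):
            d = (1.0 - w) * sdf(k0, label) + w * sdf(k1, label)
            sl[d < 0] = label
        out[:, :, k] = sl
    return LabelVolume(array=out, spacing=volume.spacing.copy(), origin=volume.origin.copy())


def resample_volume(volume: LabelVolume, target_spacing: float | np.ndarray) -> LabelVolume:
    """Nearest-neighbor resampling onto a grid of ``target_spacing`` mm.

    The new grid covers the same physical extent (voxel boxes) as the
    source; labels are categorical so only nearest-neighbor lookup is
    used.
    """
    ts = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,)).copy()
    if np.any(ts <= 0):
        raise ValueError("target spacing must be positive")
    ext_min = volume.origin - volume.spacing / 2.0
    ext_len = np.asarray(volume.shape) * volume.spacing
    new_shape = np.maximum(np.round(ext_len / ts).astype(int), 1)
    if np.any(new_shape == 1):
        warnings.warn("resampled volume degenerates to a single voxel along an axis")
    new_origin = ext_min + ts / 2.0
    idx = [
        np.clip(
            np.round((new_origin[a] + np.arange(new_shape[a]) * ts[a] - volume.origin[a]) / volume.spacing[a]).astype(int),
            0,
            volume.shape[a] - 1,
        )
        for a in range(3)
    ]
    arr = volume.array[np.ix_(idx[0], idx[1], idx[2])]
    return LabelVolume(array=arr.copy(), spacing=ts, origin=new_origin)


def dilated_mask(volume: LabelVolume, iterations: int = 3) -> np.ndarray:
    """Lumen mask dilated by ``iterations`` voxels (support band for warping)."""
    return binary_dilation(volume.array > 0, iterations=iterations)
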