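"""Surface extraction, smoothing, clipping and area reporting.

The lumen surface is extracted from the warped label volume by marching
cubes, regularized by uniform-weight Laplacian smoothing, clipped
orthogonally to the centerline to expose inlet/outlet boundaries, and
optionally extended by straight prismatic flow extensions.  Faces carry
region tags (wall, false-lumen wall, inlet, outlet, extension) that
drive the area metrics and the downstream shear-stress attribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt
from scipy.sparse import coo_matrix
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .centerline import Centerline
from .octstack import FALSE_LUMEN, TRUE_LUMEN, LabelVolume

TAG_WALL = "wall"
TAG_FALSE_LUMEN = "false_lumen_wall"
TAG_INLET = "inlet"
TAG_OUTLET = "outlet"
TAG_EXTENSION = "extension"

# Volumetric-mesh and fluid parameters exported verbatim for the external solver.
SOLVER_EXPORT_BLOCK = {
    "volume_mesh": {"scale_factor": 1.8, "boundary_layers": 6, "layer_thickness_mm": 0.15},
    "fluid": {"rho_kg_m3": 1050.0, "mu_Pa_s": 3.5e-3},
    "time": {"dt_s": 2e-3, "cardiac_cycles": 3},
}


@dataclass
class TaggedMesh:
    """Triangulated surface with per-face region tags.

    ``mesh`` is a :class:`trimesh.Trimesh` in mm; ``face_tags`` is an
    array of strings aligned with ``mesh.faces``.  ``inlet_area_mm2`` /
    ``outlet_area_mm2`` are the planar cap cross-section areas, filled
    in by :func:`clip_and_extend`.
    """

    mesh: trimesh.Trimesh
    face_tags: np.ndarray
    inlet_area_mm2: float | None = None
    outlet_area_mm2: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.face_tags = np.asarray(self.face_tags, dtype=object)
        if len(self.face_tags) != len(self.mesh.faces):
            raise ValueError("face_tags must align with mesh faces")

    @property
    def face_areas(self) -> np.ndarray:
        return self.mesh.area_faces

    def area_by_tag(self, tag: str) -> float:
        return float(self.face_areas[self.face_tags == tag].sum())

    def copy(self) -> "TaggedMesh":
        return TaggedMesh(
            mesh=self.mesh.copy(),
            face_tags=self.face_tags.copy(),
            inlet_area_mm2=self.inlet_area_mm2,
            outlet_area_mm2=self.outlet_area_mm2,
            provenance=dict(self.provenance),
        )


def label_to_surface(volume: LabelVolume, labels: tuple[int, ...] = (TRUE_LUMEN, FALSE_LUMEN)) -> TaggedMesh:
    """Marching-cubes isosurface of the selected labels at level 0.5.

    The mask is zero-padded by one voxel so the surface closes at the
    grid boundary.  Faces lying closer to false-lumen voxels than to
    true-lumen voxels are tagged ``false_lumen_wall``.
    """
    if not labels:
        raise ValueError("empty label subset")
    mask = np.isin(volume.array, labels)
    if not mask.any():
        raise ValueError("empty mask: no voxels carry the requested labels")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(volume.spacing))
    verts = verts - volume.spacing  # undo padding shift
    verts = verts + volume.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    tags = np.full(len(faces), TAG_WALL, dtype=object)
    if FALSE_LUMEN in labels and (volume.array == FALSE_LUMEN).any() and (volume.array == TRUE_LUMEN).any():
        d_true = distance_transform_edt(volume.array != TRUE_LUMEN, sampling=volume.spacing)
        d_false = distance_transform_edt(volume.array != FALSE_LUMEN, sampling=volume.spacing)
        grids = [volume.origin[a] + np.arange(volume.shape[a]) * volume.spacing[a] for a in range(3)]
        interp_t = RegularGridInterpolator(grids, d_true, bounds_error=False, fill_value=None)
        interp_f = RegularGridInterpolator(grids, d_false, bounds_error=False, fill_value=None)
        centroids = mesh.triangles_center
        tags[interp_f(centroids) < interp_t(centroids)] = TAG_FALSE_LUMEN
    return TaggedMesh(mesh=mesh, face_tags=tags)


def smooth_surface(tagged: TaggedMesh, iterations: int = 20, lamb: float = 0.5) -> TaggedMesh:
    """Uniform-weight Laplacian smoothing of vertex positions.

    Each iteration moves every vertex a fraction ``lamb`` toward the
    mean of its neighbors.  The relative volume change is recorded in
    the provenance and a shrinkage above 5% triggers a warning.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0.0 <= lamb <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    out = tagged.copy()
    if iterations == 0:
        return out
    mesh = out.mesh
    n = len(mesh.vertices)
    edges = mesh.edges_unique
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    degree[degree == 0] = 1
    v = mesh.vertices.copy()
    vol_before = abs(mesh.volume) if mesh.is_watertight else None
    for _ in range(iterations):
        v = v + lamb * (adj @ v / degree[:, None] - v)
    out.mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces.copy(), process=False)
    if vol_before and vol_before > 0:
        vol_after = abs(out.mesh.volume)
        rel = (vol_before - vol_after) / vol_before
        out.provenance["smoothing_volume_change"] = rel
        if rel > 0.05:
            warnings.warn(f"Laplacian smoothing shrank the volume by {rel:.1%}", stacklevel=2)
    return out


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary edges."""
    edges = mesh.edges_sorted
    order = np.lexsort(edges.T[::-1])
    se = edges[order]
    unique, counts = np.unique(se, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        return []
    nxt: dict[int, list[int]] = {}
    for a, b in boundary:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    unvisited = {int(v) for e in boundary for v in e}
    loops = []
    while unvisited:
        start = min(unvisited)
        loop = [start]
        unvisited.discard(start)
        prev, cur = None, start
        while True:
            candidates = [v for v in nxt[cur] if v != prev and v in unvisited]
            if not candidates:
                break
            prev, cur = cur, candidates[0]
            loop.append(cur)
            unvisited.discard(cur)
        if len(loop) >= 3:
            loops.append(np.asarray(loop, dtype=int))
    return loops


def _polygon_area_3d(points: np.ndarray) -> float:
    centroid = points.mean(axis=0)
    total = np.zeros(3)
    for i in range(len(points)):
        total += np.cross(points[i] - centroid, points[(i + 1) % len(points)] - centroid)
    return float(0.5 * np.linalg.norm(total))


def _append_cap(
    vertices: list[np.ndarray],
    faces: list[list[int]],
    tags: list[str],
    loop_pts: np.ndarray,
    tag: str,
) -> float:
    base = len(vertices)
    centroid = loop_pts.mean(axis=0)
    vertices.extend(list(loop_pts))
    vertices.append(centroid)
    n = len(loop_pts)
    for i in range(n):
        faces.append([base + i, base + (i + 1) % n, base + n])
        tags.append(tag)
    return _polygon_area_3d(loop_pts)


def clip_and_extend(
    tagged: TaggedMesh,
    centerline: Centerline,
    s_in: float,
    s_out: float,
    ext_len: float = 0.0,
) -> TaggedMesh:
    """Clip the surface orthogonally to the centerline and add extensions.

    Planar cuts are made at arc lengths ``s_in`` (proximal, becomes the
    inlet) and ``s_out`` (distal, outlet) with normals along the local
    centerline tangent.  If ``ext_len`` > 0, the open ends are extruded
    along the end tangents as straight prisms before capping.  Cap
    cross-section areas are recorded on the returned mesh.
    """
    if not s_in < s_out:
        raise ValueError("s_in must be smaller than s_out")
    lo, hi = centerline.arc_length[0], centerline.arc_length[-1]
    if s_in < lo - 1e-9 or s_out > hi + 1e-9:
        raise ValueError("clip positions outside the centerline range")
    p_in = centerline.interpolate(s_in)[0]
    p_out = centerline.interpolate(s_out)[0]
    t_in = centerline.interpolate_frame(s_in)[0]
    t_out = centerline.interpolate_frame(s_out)[0]

    mesh = tagged.mesh
    clipped = trimesh.intersections.slice_mesh_plane(mesh, plane_normal=t_in, plane_origin=p_in, cap=False)
    if clipped is None or len(clipped.faces) == 0:
        raise ValueError("inlet cut plane misses the mesh")
    clipped = trimesh.intersections.slice_mesh_plane(clipped, plane_normal=-t_out, plane_origin=p_out, cap=False)
    if clipped is None or len(clipped.faces) == 0:
        raise ValueError("outlet cut plane misses the mesh")
    clipped.merge_vertices()  # slicing duplicates vertices along the cut

    # transfer wall / false-lumen tags by nearest original face centroid
    tree = cKDTree(mesh.triangles_center)
    _, nearest = tree.query(clipped.triangles_center)
    new_tags = tagged.face_tags[nearest].copy()

    vertices = list(np.asarray(clipped.vertices))
    faces = [list(f) for f in clipped.faces]
    tags = list(new_tags)

    loops = _boundary_loops(clipped)
    if len(loops) < 2:
        raise ValueError(f"expected two open ends after clipping, found {len(loops)}")
    # classify each loop to the closer cut plane
    areas = {"inlet": 0.0, "outlet": 0.0}
    for loop_idx in loops:
        lp = clipped.vertices[loop_idx]
        c = lp.mean(axis=0)
        end = "inlet" if np.linalg.norm(c - p_in) < np.linalg.norm(c - p_out) else "outlet"
        outward = -t_in if end == "inlet" else t_out
        ring = lp
        if ext_len > 0:
            # straight prismatic extension: extrude the boundary ring outward
            base = len(vertices)
            far = lp + outward * ext_len
            vertices.extend(list(far))
            n = len(loop_idx)
            for i in range(n):
                a, b = int(loop_idx[i]), int(loop_idx[(i + 1) % n])
                fa, fb = base + i, base + (i + 1) % n
                faces.append([a, b, fb])
                faces.append([a, fb, fa])
                tags.extend([TAG_EXTENSION, TAG_EXTENSION])
            ring = far
        cap_tag = TAG_INLET if end == "inlet" else TAG_OUTLET
        areas[end] = _append_cap(vertices, faces, tags, ring, cap_tag)
    out_mesh = trimesh.Trimesh(vertices=np.asarray(vertices), faces=np.asarray(faces), process=False)
    return TaggedMesh(
        mesh=out_mesh,
        face_tags=np.asarray(tags, dtype=object),
        inlet_area_mm2=areas["inlet"],
        outlet_area_mm2=areas["outlet"],
        provenance=dict(tagged.provenance, clip={"s_in": s_in, "s_out": s_out, "ext_len": ext_len}),
    )


def surface_areas(tagged: TaggedMesh) -> dict[str, float]:
    """Area metrics by region tag.

    ``total_cm2`` sums wall and false-lumen wall faces (caps and flow
    extensions excluded); inlet/outlet are the planar cap areas in mm^2.
    """
    known = {TAG_WALL, TAG_FALSE_LUMEN, TAG_INLET, TAG_OUTLET, TAG_EXTENSION}
    present = set(tagged.face_tags.tolist())
    if not present <= known:
        raise ValueError(f"untagged or unknown face tags: {present - known}")
    wall = tagged.area_by_tag(TAG_WALL)
    false_lumen = tagged.area_by_tag(TAG_FALSE_LUMEN)
    inlet = tagged.inlet_area_mm2 if tagged.inlet_area_mm2 is not None else tagged.area_by_tag(TAG_INLET)
    outlet = tagged.outlet_area_mm2 if tagged.outlet_area_mm2 is not None else tagged.area_by_tag(TAG_OUTLET)
    return {
        "total_cm2": (wall + false_lumen) / 100.0,
        "false_lumen_cm2": false_lumen / 100.0,
        "inlet_mm2": float(inlet),
        "outlet_mm2": float(outlet),
    }


def swept_tube_mesh(
    centerline: Centerline,
    radius_fn,
    n_theta: int = 64,
    cap_ends: bool = True,
) -> TaggedMesh:
    """Analytic tube surface swept along a centerline with RMF frames.

    ``radius_fn`` maps arc length (mm) to lumen radius (mm).  Used by
    the phantom generator to provide ground-truth surfaces.
    """
    s = centerline.arc_length
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    rings = []
    for i in range(len(s)):
        r = radius_fn(s[i])
        ring = (
            centerline.points[i]
            + np.outer(ct, centerline.normals[i]) * r
            + np.outer(st, centerline.binormals[i]) * r
        )
        rings.append(ring)
    vertices = np.vstack(rings)
    faces = []
    for i in range(len(s) - 1):
        base = i * n_theta
        for j in range(n_theta):
            a, b = base + j, base + (j + 1) % n_theta
            c, d = a + n_theta, b + n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    tags = [TAG_WALL] * len(faces)
    verts_list = list(vertices)
    if cap_ends:
        _append_cap(verts_list, faces, tags, rings[0][::-1], TAG_INLET)
        _append_cap(verts_list, faces, tags, rings[-1], TAG_OUTLET)
    mesh = trimesh.Trimesh(vertices=np.asarray(verts_list), faces=np.asarray(faces), process=False)
    return TaggedMesh(mesh=mesh, face_tags=np.asarray(tags, dtype=object))
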