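"""Plain-text and standard-format serialization of pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .centerline import Centerline
from .meshing import TaggedMesh
from .octstack import ContourSet, FrameQuality, LabelVolume


def write_centerline_csv(cl: Centerline, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "s_mm": cl.arc_length,
            "x": cl.points[:, 0],
            "y": cl.points[:, 1],
            "z": cl.points[:, 2],
            "tx": cl.tangents[:, 0],
            "ty": cl.tangents[:, 1],
            "tz": cl.tangents[:, 2],
            "nx": cl.normals[:, 0],
            "ny": cl.normals[:, 1],
            "nz": cl.normals[:, 2],
            "bx": cl.binormals[:, 0],
            "by": cl.binormals[:, 1],
            "bz": cl.binormals[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_centerline_csv(path: str | Path) -> Centerline:
    df = pd.read_csv(path)
    return Centerline(
        points=df[["x", "y", "z"]].to_numpy(),
        arc_length=df["s_mm"].to_numpy(),
        tangents=df[["tx", "ty", "tz"]].to_numpy(),
        normals=df[["nx", "ny", "nz"]].to_numpy(),
        binormals=df[["bx", "by", "bz"]].to_numpy(),
    )


def write_contours_csv(frames: list[ContourSet], path: str | Path) -> None:
    rows = []
    for f in frames:
        if f.quality == FrameQuality.EXCLUDED:
            rows.append({"frame_index": f.frame_index, "region_tag": -1, "x_mm": np.nan, "y_mm": np.nan})
            continue
        for tag, pts in f.contours:
            for x, y in pts:
                rows.append({"frame_index": f.frame_index, "region_tag": tag, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours_csv(path: str | Path) -> list[ContourSet]:
    df = pd.read_csv(path)
    frames = []
    for k, grp in df.groupby("frame_index"):
        if (grp["region_tag"] == -1).all():
            frames.append(ContourSet(frame_index=int(k), quality=FrameQuality.EXCLUDED))
            continue
        contours = []
        for tag, sub in grp.groupby("region_tag"):
            contours.append((int(tag), sub[["x_mm", "y_mm"]].to_numpy()))
        frames.append(ContourSet(frame_index=int(k), contours=contours))
    return frames


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """NIfTI with voxel spacing in the affine and origin in the translation."""
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.array.astype(np.uint8), affine), str(path))


def read_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    affine = img.affine
    return LabelVolume(
        array=np.asarray(img.dataobj, dtype=np.uint8),
        spacing=np.diag(affine)[:3].copy(),
        origin=affine[:3, 3].copy(),
    )


def write_mesh(tagged: TaggedMesh, stl_path: str | Path, tags_path: str | Path | None = None) -> None:
    tagged.mesh.export(str(stl_path))
    if tags_path is not None:
        payload = {
            "face_tags": tagged.face_tags.tolist(),
            "inlet_area_mm2": tagged.inlet_area_mm2,
            "outlet_area_mm2": tagged.outlet_area_mm2,
            "provenance": tagged.provenance,
        }
        Path(tags_path).write_text(json.dumps(payload))


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
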