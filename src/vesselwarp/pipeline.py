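"""End-to-end orchestration: phantom -> reconstruction -> hemodynamic report.

One run executes the full chain on a synthetic phantom with known
ground truth: biplane projection and calibration, centerline
triangulation, OCT-stack rasterization, straight-to-anatomical label
warping, surface meshing with clipping, boundary-condition calibration,
and the TAWSS adverse-area report, writing every artifact plus a
provenance record into an immutable output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .biplane import BoundarySpline, Side, View, calibrate_view, extract_centerline, triangulate_boundaries
from .hemodynamics import (
    DEFAULT_PERIOD_S,
    boundary_condition_bundle,
    build_waveform,
    calibrate_windkessel,
    waveform_to_flow,
    windkessel_pressure,
)
from .meshing import clip_and_extend, label_to_surface, smooth_surface, surface_areas
from .octstack import contours_to_labels, interpolate_missing, resample_volume
from .phantom import (
    Dissection,
    PhantomSpec,
    Stenosis,
    ideal_projection_geometry,
    make_phantom,
    project_phantom,
    render_oct_stack,
)
from .tawss import adverse_areas, compute_tawss, poiseuille_field
from .warp import (
    align_centerlines,
    build_slice_map,
    centerline_from_label,
    default_target_grid,
    forward_field,
    invert_field,
    warp_labels,
)

logger = logging.getLogger("vesselwarp")

# defaults not fixed by any measurement protocol are flagged "assumed"
ASSUMED_DEFAULTS = {
    "smoothing_iterations": 20,
    "smoothing_lambda": 0.5,
    "extension_diameters": 3.0,
    "cardiac_period_s": DEFAULT_PERIOD_S,
    "false_lumen_attenuation": 0.05,
    "centerline_smoothing_mm2": 0.1,
}


@dataclass
class RunConfig:
    """Pipeline configuration; every field has a working default."""

    # phantom
    centerline_kind: str = "arc"
    length_mm: float = 40.0
    radius_mm: float = 2.0
    bend_radius_mm: float = 60.0
    stenosis: dict | None = None
    dissection: dict | None = None
    seed: int = 0
    # projections
    view_azimuths_deg: tuple[float, float] = (0.0, 90.0)
    detection_noise_px: float = 0.0
    # OCT stack
    frame_spacing_mm: float = 0.2
    oct_pixel_mm: float = 0.05
    iso_spacing_mm: float = 0.12
    dropout_frames: list[int] = field(default_factory=list)
    # meshing
    smooth_iterations: int = 20
    smooth_lambda: float = 0.5
    clip_margin_mm: float = 3.0
    extension_mm: float = 0.0
    # hemodynamics
    phase_type: str = "triphasic"
    psv_cm_s: float = 88.30
    mdv_cm_s: float = -14.90
    period_s: float = DEFAULT_PERIOD_S
    # reporting
    low_tawss_pa: float = 0.5
    high_tawss_pa: float = 7.0
    false_lumen_attenuation: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _phantom_spec(config: RunConfig) -> PhantomSpec:
    stenosis = Stenosis(**config.stenosis) if config.stenosis else None
    dissection = Dissection(**config.dissection) if config.dissection else None
    return PhantomSpec(
        centerline_kind=config.centerline_kind,
        length=config.length_mm,
        radius=config.radius_mm,
        bend_radius=config.bend_radius_mm,
        stenosis=stenosis,
        dissection=dissection,
        seed=config.seed,
        detection_sigma_px=config.detection_noise_px,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages, write artifacts to ``out_dir``, return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    def stage(name: str):
        logger.info("stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    with stage("phantom"):
        spec = _phantom_spec(config)
        truth = make_phantom(spec, voxel_size=(config.oct_pixel_mm, config.oct_pixel_mm, config.frame_spacing_mm))
        report["phantom"] = {
            "total_area_cm2": truth.total_area_cm2,
            "false_lumen_area_cm2": truth.false_lumen_area_cm2,
        }

    with stage("project"):
        geom_a0 = ideal_projection_geometry(config.view_azimuths_deg[0], target=(0, 0, config.length_mm / 2))
        geom_b0 = ideal_projection_geometry(config.view_azimuths_deg[1], target=(0, 0, config.length_mm / 2))
        view_a, view_b = project_phantom(truth, geom_a0, geom_b0, noise_px=config.detection_noise_px)

    with stage("calibrate"):
        geom_a = calibrate_view(truth.fiducials_3d, view_a.fiducials_px)
        geom_b = calibrate_view(truth.fiducials_3d, view_b.fiducials_px)
        report["calibration_rms_px"] = [geom_a.reprojection_rms, geom_b.reprojection_rms]

    with stage("centerline"):
        splines = [
            BoundarySpline(view_a.boundary_left_px, Side.LEFT, View.A),
            BoundarySpline(view_a.boundary_right_px, Side.RIGHT, View.A),
            BoundarySpline(view_b.boundary_left_px, Side.LEFT, View.B),
            BoundarySpline(view_b.boundary_right_px, Side.RIGHT, View.B),
        ]
        b_left, b_right = triangulate_boundaries(splines, geom_a, geom_b)
        xray_cl = extract_centerline(b_left, b_right, n_samples=max(len(b_left), 200))
        vio.write_centerline_csv(xray_cl, out / "xray_centerline.csv")

    with stage("rasterize"):
        frames = render_oct_stack(truth, frame_spacing=config.frame_spacing_mm, pixel_size=config.oct_pixel_mm,
                                  dropout=set(config.dropout_frames))
        grid_extent = int(np.ceil(2 * (config.radius_mm + 1.5) / config.oct_pixel_mm))
        straight = contours_to_labels(frames, config.oct_pixel_mm, config.frame_spacing_mm, grid_extent)
        if config.dropout_frames:
            annotated = [f.frame_index for f in frames if f.quality.value == "ok"]
            straight = interpolate_missing(straight, annotated)
        iso = resample_volume(straight, config.iso_spacing_mm)

    with stage("warp"):
        oct_cl, slice_idx = centerline_from_label(iso, return_indices=True)
        alignment = align_centerlines(oct_cl, xray_cl)
        smap = build_slice_map(oct_cl, xray_cl, alignment, source_z_index=slice_idx)
        fwd = forward_field(iso, smap)
        grid = default_target_grid(fwd)
        inv = invert_field(fwd, grid)
        warped = warp_labels(iso, inv)
        vio.write_label_volume(warped, out / "warped_labels.nii.gz")
        report["inverse_residual_mm"] = inv.residual

    with stage("mesh"):
        surface = label_to_surface(warped)
        surface = smooth_surface(surface, iterations=config.smooth_iterations, lamb=config.smooth_lambda)
        s0 = xray_cl.arc_length[0] + config.clip_margin_mm
        s1 = xray_cl.arc_length[-1] - config.clip_margin_mm
        clipped = clip_and_extend(surface, xray_cl, s0, s1, ext_len=config.extension_mm)
        areas = surface_areas(clipped)
        vio.write_mesh(clipped, out / "surface.stl", out / "surface_tags.json")
        report["areas"] = areas

    with stage("boundary_conditions"):
        wave = build_waveform(config.phase_type, config.psv_cm_s, config.mdv_cm_s, period=config.period_s)
        flow = waveform_to_flow(wave, areas["inlet_mm2"])
        rc = calibrate_windkessel(flow)
        trace = windkessel_pressure(flow, rc)
        bundle = boundary_condition_bundle(wave, flow, rc, areas["inlet_mm2"])
        vio.write_json(bundle, out / "boundary_conditions.json")
        report["mean_flow_ml_min"] = flow.mean_flow_ml_min
        report["windkessel"] = {"R": rc.R, "C": rc.C, "p_sys": trace.p_sys, "p_dia": trace.p_dia}

    with stage("tawss"):
        series = poiseuille_field(clipped, xray_cl, flow, attenuation=config.false_lumen_attenuation)
        tawss = compute_tawss(series)
        adverse = adverse_areas(tawss, clipped, config.low_tawss_pa, config.high_tawss_pa)
        report["tawss"] = adverse.as_dict()
        vio.write_json(report["tawss"], out / "tawss_report.json")

    with stage("provenance"):
        provenance = {
            "config": asdict(config),
            "seed": config.seed,
            "assumed_defaults": ASSUMED_DEFAULTS,
            "versions": _versions(),
        }
        vio.write_json(provenance, out / "provenance.json")

    vio.write_json(report, out / "report.json")
    return report


def _versions() -> dict:
    import numpy
    import scipy
    import skimage
    import trimesh

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "trimesh": trimesh.__version__,
    }


def load_report(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "report.json").read_text())
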