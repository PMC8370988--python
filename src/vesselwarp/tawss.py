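"""Time-averaged wall shear stress mapping and group statistics.

TAWSS is the period average of the WSS magnitude per surface face;
faces below 0.5 Pa or above 7 Pa are classified as adversely loaded
(atheroprone), with strict inequalities so boundary-equal faces count
as normal.  Affected areas are attributed to the false-lumen wall via
the mesh face tags.  Group comparisons use pooled-variance two-sample
Student t-tests (Welch available by flag).

A per-slice Poiseuille field generator provides an analytic WSS time
series for phantoms: each wall face receives the fully developed value
for the local lumen radius, with false-lumen faces attenuated to
emulate stagnant false-lumen flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .centerline import Centerline
from .hemodynamics import BLOOD_MU_PA_S, Waveform
from .meshing import TAG_FALSE_LUMEN, TAG_WALL, TaggedMesh

LOW_TAWSS_PA = 0.5
HIGH_TAWSS_PA = 7.0
FALSE_LUMEN_ATTENUATION = 0.05


@dataclass
class WSSTimeSeries:
    """Per-face WSS magnitude (Pa) sampled over one cardiac period."""

    mesh: TaggedMesh
    times: np.ndarray  # (nt,) s, strictly increasing, spans one period
    wss: np.ndarray  # (nt, n_faces), Pa, non-negative

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wss = np.asarray(self.wss, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.wss.shape != (len(self.times), len(self.mesh.mesh.faces)):
            raise ValueError("wss array must be (n_times, n_faces)")
        if np.any(self.wss < 0):
            raise ValueError("WSS magnitudes must be non-negative")


def compute_tawss(series: WSSTimeSeries) -> np.ndarray:
    """Per-face TAWSS via the trapezoidal rule over one period (Pa)."""
    if len(series.times) < 2:
        raise ValueError("need at least two time samples")
    span = series.times[-1] - series.times[0]
    return np.trapezoid(series.wss, series.times, axis=0) / span


@dataclass
class AdverseAreaReport:
    """Wall areas classified by TAWSS thresholds (strict inequalities)."""

    tawss: np.ndarray  # per wall face, Pa
    low_area_cm2: float
    high_area_cm2: float
    normal_area_cm2: float
    wall_area_cm2: float
    false_lumen_area_cm2: float
    low_area_in_false_lumen_cm2: float
    low_fraction: float = field(init=False)
    high_fraction: float = field(init=False)
    false_lumen_low_coverage: float = field(init=False)

    def __post_init__(self) -> None:
        if abs(self.low_area_cm2 + self.high_area_cm2 + self.normal_area_cm2 - self.wall_area_cm2) > 1e-9 * max(self.wall_area_cm2, 1.0):
            raise ValueError("adverse-area partition does not conserve the wall area")
        self.low_fraction = self.low_area_cm2 / self.wall_area_cm2 if self.wall_area_cm2 else 0.0
        self.high_fraction = self.high_area_cm2 / self.wall_area_cm2 if self.wall_area_cm2 else 0.0
        self.false_lumen_low_coverage = (
            self.low_area_in_false_lumen_cm2 / self.false_lumen_area_cm2
            if self.false_lumen_area_cm2
            else 0.0
        )

    def as_dict(self) -> dict:
        return {
            "low_area_cm2": self.low_area_cm2,
            "high_area_cm2": self.high_area_cm2,
            "normal_area_cm2": self.normal_area_cm2,
            "wall_area_cm2": self.wall_area_cm2,
            "false_lumen_area_cm2": self.false_lumen_area_cm2,
            "low_area_in_false_lumen_cm2": self.low_area_in_false_lumen_cm2,
            "low_fraction": self.low_fraction,
            "high_fraction": self.high_fraction,
            "false_lumen_low_coverage": self.false_lumen_low_coverage,
        }


def adverse_areas(
    tawss: np.ndarray,
    mesh: TaggedMesh,
    low_thresh: float = LOW_TAWSS_PA,
    high_thresh: float = HIGH_TAWSS_PA,
) -> AdverseAreaReport:
    """Classify wall faces by TAWSS and sum areas (cm^2).

    ``tawss`` must cover all wall faces (caps and extensions excluded);
    classification is strict: exactly-threshold faces are normal.
    """
    if not low_thresh < high_thresh:
        raise ValueError("low threshold must be below high threshold")
    wall = np.isin(mesh.face_tags, [TAG_WALL, TAG_FALSE_LUMEN])
    values = np.asarray(tawss, dtype=float)
    if values.shape[0] == len(mesh.face_tags):
        values = values[wall]
    elif values.shape[0] != int(wall.sum()):
        raise ValueError("tawss must be defined on all wall faces")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing (non-finite) TAWSS values on wall faces")
    areas = mesh.face_areas[wall] / 100.0  # mm^2 -> cm^2
    fl = (mesh.face_tags == TAG_FALSE_LUMEN)[wall]
    low = values < low_thresh
    high = values > high_thresh
    normal = ~(low | high)
    return AdverseAreaReport(
        tawss=values,
        low_area_cm2=float(areas[low].sum()),
        high_area_cm2=float(areas[high].sum()),
        normal_area_cm2=float(areas[normal].sum()),
        wall_area_cm2=float(areas.sum()),
        false_lumen_area_cm2=float(areas[fl].sum()),
        low_area_in_false_lumen_cm2=float(areas[low & fl].sum()),
    )


def group_summary(
    groups: dict[str, np.ndarray | list[float]],
    alpha: float = 0.05,
    welch: bool = False,
) -> dict:
    """Mean, sample SD and pairwise unpaired t-tests per group.

    Returns ``{"groups": {name: {mean, sd, n}}, "tests": {(a, b):
    {t, p, significant}}}`` with the sample (n-1) standard deviation and
    pooled-variance Student t-tests (``welch=True`` switches to the
    unequal-variance form).
    """
    summary: dict = {"groups": {}, "tests": {}}
    arrays = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        arrays[name] = arr
        summary["groups"][name] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
            "n": int(len(arr)),
        }
    for a, b in combinations(arrays, 2):
        t, p = stats.ttest_ind(arrays[a], arrays[b], equal_var=not welch)
        summary["tests"][(a, b)] = {
            "t": float(t),
            "p": float(p),
            "significant": bool(p < alpha),
        }
    return summary


def poiseuille_field(
    mesh: TaggedMesh,
    centerline: Centerline,
    q: Waveform,
    mu_pa_s: float = BLOOD_MU_PA_S,
    attenuation: float = FALSE_LUMEN_ATTENUATION,
    n_times: int = 50,
    n_bins: int = 50,
) -> WSSTimeSeries:
    """Analytic per-slice Poiseuille WSS time series on a tagged mesh.

    Wall faces are binned by their arc-length position along the
    centerline; each bin's effective lumen radius is the median radial
    distance of its true-lumen wall faces to the centerline, and every
    face in the bin receives ``tau(t) = 4 mu Q(t) / (pi r^3)``.
    False-lumen faces are attenuated by ``attenuation`` to emulate the
    near-stagnant flow inside dissection channels.
    """
    if q.kind != "flow":
        raise ValueError("poiseuille_field expects a flow waveform")
    wall = np.isin(mesh.face_tags, [TAG_WALL, TAG_FALSE_LUMEN])
    centroids = mesh.mesh.triangles_center[wall]
    fl = (mesh.face_tags == TAG_FALSE_LUMEN)[wall]
    tree = cKDTree(centerline.points)
    dist, nearest = tree.query(centroids)
    s = centerline.arc_length[nearest]
    edges = np.linspace(centerline.arc_length[0], centerline.arc_length[-1], n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    radius_of_bin = np.full(n_bins, np.nan)
    for b in range(n_bins):
        in_bin = (bin_of == b) & ~fl
        if in_bin.any():
            radius_of_bin[b] = np.median(dist[in_bin])
    # bins with only false-lumen faces inherit the nearest true-lumen radius
    valid = np.nonzero(~np.isnan(radius_of_bin))[0]
    if len(valid) == 0:
        raise ValueError("no true-lumen wall faces to estimate slice radii")
    filled = radius_of_bin[valid[np.argmin(np.abs(np.arange(n_bins)[:, None] - valid[None, :]), axis=1)]]
    r_face = filled[bin_of]
    if np.any(r_face <= 0):
        raise ValueError("slice with zero effective radius")
    times = np.linspace(0.0, q.period, n_times)
    q_t = q(times)
    tau = 4.0 * mu_pa_s * np.abs(q_t)[:, None] / (np.pi * r_face[None, :] ** 3)
    tau[:, fl] *= attenuation
    wss = np.zeros((n_times, len(mesh.face_tags)))
    wss[:, wall] = tau
    return WSSTimeSeries(mesh=mesh, times=times, wss=wss)
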