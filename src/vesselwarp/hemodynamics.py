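"""Inlet waveforms, Windkessel outlet calibration, and the Poiseuille
wall-shear oracle.

Duplex-ultrasound velocimetry provides only the waveform extrema (peak
systolic and minimum diastolic velocity), so inlet waveforms are built
from a piecewise-sinusoid template — forward systolic lobe, reverse
early-diastolic lobe and a smaller forward late-diastolic lobe for the
triphasic pattern of healthy peripheral arteries; a single forward lobe
plus a low secondary lobe for the post-stenotic monophasic pattern —
scaled so the extrema match the measured PSV/MDV exactly.

The outlet is a two-element Windkessel, C dP/dt = Q(t) - P/R, calibrated
so its periodic pressure solution spans an idealized 120/80 mmHg
profile.  Internal units are mm-s-MPa (R in MPa*s/mm^3, C in mm^3/MPa);
clinical units are converted at the interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .units import mm3_s_to_ml_min, mmhg_to_mpa, mpa_to_mmhg

DEFAULT_PERIOD_S = 1.0
DEFAULT_DT_S = 2e-3
BLOOD_MU_PA_S = 3.5e-3
BLOOD_RHO_KG_M3 = 1050.0

# phase fractions of the cardiac period for the piecewise-sinusoid template
TRIPHASIC_FRACTIONS = {"systole": 0.30, "reverse": 0.15, "late_forward": 0.25}
LATE_FORWARD_AMPLITUDE = 0.20  # of PSV
MONOPHASIC_FRACTIONS = {"systole": 0.35}
MONOPHASIC_PLATEAU = 0.05  # of PSV, amplitude of the low secondary lobe


@dataclass
class Waveform:
    """Periodic waveform: velocity (cm/s) or volumetric flow (mm^3/s)."""

    period: float
    times: np.ndarray
    values: np.ndarray
    kind: str = "velocity"  # velocity | flow
    phase_type: str = "triphasic"
    psv: Optional[float] = None
    mdv: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("waveform times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] >= self.period:
            raise ValueError("waveform times must lie in [0, period)")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        """Periodic linear interpolation."""
        tp = np.mod(np.asarray(t, dtype=float), self.period)
        times = np.concatenate([self.times, [self.period]])
        values = np.concatenate([self.values, [self.values[0]]])
        return np.interp(tp, times, values)

    @property
    def time_average(self) -> float:
        times = np.concatenate([self.times, [self.period]])
        values = np.concatenate([self.values, [self.values[0]]])
        return float(np.trapezoid(values, times) / self.period)

    @property
    def mean_flow_ml_min(self) -> float:
        if self.kind != "flow":
            raise ValueError("mean_flow_ml_min requires a flow waveform")
        return mm3_s_to_ml_min(self.time_average)


def build_waveform(
    phase_type: str,
    psv: float,
    mdv: float = 0.0,
    period: float = DEFAULT_PERIOD_S,
    n_samples: int = 1000,
) -> Waveform:
    """Piecewise-sinusoid velocity template scaled to the DUS extrema.

    ``psv`` and ``mdv`` in cm/s.  Triphasic requires a reverse-flow
    phase (mdv < 0); the monophasic template never goes negative and
    rejects a negative mdv.  Extrema of the returned samples equal
    psv/mdv exactly (the peak times are inserted into the sample grid).
    """
    if psv <= 0:
        raise ValueError("peak systolic velocity must be positive")
    if phase_type not in ("monophasic", "triphasic"):
        raise ValueError(f"unknown phase type {phase_type!r}")
    if phase_type == "monophasic" and mdv < 0:
        raise ValueError("monophasic waveform cannot have a negative minimum diastolic velocity")
    if phase_type == "triphasic" and mdv >= 0:
        raise ValueError("triphasic waveform requires a reverse phase (mdv < 0)")

    if phase_type == "triphasic":
        f1 = TRIPHASIC_FRACTIONS["systole"]
        f2 = TRIPHASIC_FRACTIONS["reverse"]
        f3 = TRIPHASIC_FRACTIONS["late_forward"]
        breaks = np.array([0.0, f1, f1 + f2, f1 + f2 + f3, 1.0]) * period
        peaks = [0.5 * (breaks[0] + breaks[1]), 0.5 * (breaks[1] + breaks[2]), 0.5 * (breaks[2] + breaks[3])]

        def template(t: np.ndarray) -> np.ndarray:
            v = np.zeros_like(t)
            m = (t >= breaks[0]) & (t < breaks[1])
            v[m] = psv * np.sin(np.pi * (t[m] - breaks[0]) / (breaks[1] - breaks[0]))
            m = (t >= breaks[1]) & (t < breaks[2])
            v[m] = mdv * np.sin(np.pi * (t[m] - breaks[1]) / (breaks[2] - breaks[1]))
            m = (t >= breaks[2]) & (t < breaks[3])
            v[m] = LATE_FORWARD_AMPLITUDE * psv * np.sin(np.pi * (t[m] - breaks[2]) / (breaks[3] - breaks[2]))
            return v

    else:
        f1 = MONOPHASIC_FRACTIONS["systole"]
        breaks = np.array([0.0, f1, 1.0]) * period
        peaks = [0.5 * (breaks[0] + breaks[1]), 0.5 * (breaks[1] + breaks[2])]

        def template(t: np.ndarray) -> np.ndarray:
            v = np.zeros_like(t)
            m = (t >= breaks[0]) & (t < breaks[1])
            v[m] = psv * np.sin(np.pi * (t[m] - breaks[0]) / (breaks[1] - breaks[0]))
            m = t >= breaks[1]
            v[m] = MONOPHASIC_PLATEAU * psv * np.sin(np.pi * (t[m] - breaks[1]) / (breaks[2] - breaks[1]))
            return v

    times = np.unique(np.concatenate([np.linspace(0.0, period, n_samples, endpoint=False), peaks, breaks[:-1]]))
    times = times[times < period]
    return Waveform(
        period=period,
        times=times,
        values=template(times),
        kind="velocity",
        phase_type=phase_type,
        psv=psv,
        mdv=mdv if phase_type == "triphasic" else max(mdv, 0.0),
    )


def waveform_to_flow(w: Waveform, inlet_area_mm2: float) -> Waveform:
    """Convert a spatial-mean velocity waveform (cm/s) to flow (mm^3/s)."""
    if w.kind != "velocity":
        raise ValueError("expected a velocity waveform")
    if inlet_area_mm2 <= 0:
        raise ValueError("inlet area must be positive")
    q = w.values * 10.0 * inlet_area_mm2  # cm/s -> mm/s, times mm^2
    return Waveform(
        period=w.period,
        times=w.times.copy(),
        values=q,
        kind="flow",
        phase_type=w.phase_type,
        psv=w.psv,
        mdv=w.mdv,
    )


def parabolic_profile(
    v_mean: float, cap: trimesh.Trimesh
) -> tuple[np.ndarray, dict]:
    """Per-vertex parabolic velocity profile over a planar inlet cap.

    ``v(r) = 2 v_mean (1 - (r / R_eff)^2)`` around the cap centroid with
    ``R_eff`` the maximal centroid distance, then rescaled so the
    face-integrated flux equals ``v_mean * area`` exactly.  Returns the
    per-vertex magnitudes (same units as ``v_mean``) and a report with
    the flux and rescale factor.  Multi-component caps are rejected.
    """
    if len(cap.split(only_watertight=False)) > 1:
        raise ValueError("inlet cap has multiple connected components")
    centroid = cap.vertices.mean(axis=0)
    r = np.linalg.norm(cap.vertices - centroid, axis=1)
    r_eff = r.max()
    if r_eff <= 0:
        raise ValueError("degenerate cap")
    v = 2.0 * v_mean * np.clip(1.0 - (r / r_eff) ** 2, 0.0, None)
    face_mean = v[cap.faces].mean(axis=1)
    flux = float((face_mean * cap.area_faces).sum())
    target = v_mean * cap.area
    scale = target / flux if flux != 0 else 0.0
    return v * scale, {"area_mm2": float(cap.area), "flux_target": target, "rescale": scale, "r_eff": float(r_eff)}


@dataclass
class WindkesselRC:
    """Two-element outlet model parameters in mm-s-MPa units."""

    R: float  # MPa*s/mm^3
    C: float  # mm^3/MPa

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0:
            raise ValueError("Windkessel R and C must be positive")


@dataclass
class PressureTrace:
    """One periodic cycle of the outlet pressure (mmHg)."""

    times: np.ndarray
    pressure_mmhg: np.ndarray
    p_sys: float
    p_dia: float
    n_cycles: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_sys < self.p_dia:
            raise ValueError("systolic pressure below diastolic")


def windkessel_pressure(
    q: Waveform,
    rc: WindkesselRC,
    p0_mmhg: float = 80.0,
    dt: float = DEFAULT_DT_S,
    max_cycles: int = 20,
    tol_mmhg: float = 0.1,
) -> PressureTrace:
    """Integrate C dP/dt = Q(t) - P/R to the periodic solution.

    Classical RK4 with fixed step ``dt`` from P(0) = ``p0_mmhg``,
    repeating cardiac cycles until the cycle-to-cycle maximum pressure
    difference drops below ``tol_mmhg`` (raising after ``max_cycles``).
    Only the converged last cycle is returned.
    """
    if q.kind != "flow":
        raise ValueError("windkessel_pressure expects a flow waveform (mm^3/s)")
    n_steps = int(round(q.period / dt))
    if n_steps < 4:
        raise ValueError("time step too large for the cardiac period")
    ts = np.arange(n_steps + 1) * dt

    def rhs(t: float, p: float) -> float:
        return (float(q(t)) - p / rc.R) / rc.C

    p = mmhg_to_mpa(p0_mmhg)
    prev_cycle = None
    for cycle in range(1, max_cycles + 1):
        trace = np.empty(n_steps + 1)
        trace[0] = p
        for i in range(n_steps):
            t = ts[i]
            k1 = rhs(t, p)
            k2 = rhs(t + dt / 2, p + dt / 2 * k1)
            k3 = rhs(t + dt / 2, p + dt / 2 * k2)
            k4 = rhs(t + dt, p + dt * k3)
            p = p + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            trace[i + 1] = p
        if prev_cycle is not None:
            if mpa_to_mmhg(float(np.abs(trace - prev_cycle).max())) < tol_mmhg:
                p_mmhg = mpa_to_mmhg(1.0) * trace
                return PressureTrace(
                    times=ts,
                    pressure_mmhg=p_mmhg,
                    p_sys=float(p_mmhg.max()),
                    p_dia=float(p_mmhg.min()),
                    n_cycles=cycle,
                )
        prev_cycle = trace
    raise RuntimeError(f"Windkessel pressure did not reach a periodic state in {max_cycles} cycles")


def calibrate_windkessel(
    q: Waveform,
    p_sys_mmhg: float = 120.0,
    p_dia_mmhg: float = 80.0,
    tol_mmhg: float = 1e-3,
    max_iter: int = 50,
) -> WindkesselRC:
    """Solve for (R, C) so the periodic pressure spans p_sys / p_dia.

    Damped Newton iteration in log-parameters on the periodic-solution
    map, with a finite-difference Jacobian.  The mean-pressure balance
    ``mean(P) = R * mean(Q)`` seeds R; the sinusoidal amplitude relation
    seeds C.  A constant flow leaves C unidentifiable and raises.
    """
    if p_sys_mmhg <= p_dia_mmhg:
        raise ValueError("infeasible targets: systolic must exceed diastolic pressure")
    q_mean = q.time_average
    if q_mean <= 0:
        raise ValueError("flow waveform must have a positive time average")
    q_amp = 0.5 * (float(q.values.max()) - float(q.values.min()))
    if q_amp < 1e-9 * abs(q_mean):
        raise ValueError("constant flow: Windkessel capacitance is unidentifiable")

    p_mean_target = mmhg_to_mpa(0.5 * (p_sys_mmhg + p_dia_mmhg))
    pulse = mmhg_to_mpa(p_sys_mmhg - p_dia_mmhg)
    r0 = p_mean_target / q_mean
    omega = 2.0 * np.pi / q.period
    ratio = max((2.0 * r0 * q_amp / pulse) ** 2 - 1.0, 0.25)
    c0 = np.sqrt(ratio) / (omega * r0)
    x = np.log(np.array([r0, c0]))

    def residual(xv: np.ndarray) -> np.ndarray:
        rc = WindkesselRC(R=float(np.exp(xv[0])), C=float(np.exp(xv[1])))
        tr = windkessel_pressure(q, rc, p0_mmhg=p_dia_mmhg)
        return np.array([tr.p_sys - p_sys_mmhg, tr.p_dia - p_dia_mmhg])

    f = residual(x)
    for _ in range(max_iter):
        if np.abs(f).max() < tol_mmhg:
            return WindkesselRC(R=float(np.exp(x[0])), C=float(np.exp(x[1])))
        jac = np.empty((2, 2))
        h = 1e-4
        for j in range(2):
            xp = x.copy()
            xp[j] += h
            jac[:, j] = (residual(xp) - f) / h
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Jacobian in Windkessel calibration") from exc
        lam = 1.0
        for _ in range(8):
            x_new = x + lam * step
            f_new = residual(x_new)
            if np.linalg.norm(f_new) < np.linalg.norm(f):
                x, f = x_new, f_new
                break
            lam *= 0.5
        else:
            raise RuntimeError("Windkessel calibration stalled (no descent step)")
    if np.abs(f).max() < tol_mmhg:
        return WindkesselRC(R=float(np.exp(x[0])), C=float(np.exp(x[1])))
    raise RuntimeError(f"Windkessel calibration did not converge: residual {f} mmHg")


def poiseuille_wss(q_mm3_s: float, radius_mm: float, mu_pa_s: float = BLOOD_MU_PA_S) -> float:
    """Fully developed Poiseuille wall shear stress tau = 4 mu Q / (pi r^3), Pa.

    With Q in mm^3/s and r in mm, Q / r^3 carries 1/s, so the product
    with mu (Pa*s) is already in Pa.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    return 4.0 * mu_pa_s * q_mm3_s / (np.pi * radius_mm**3)


def boundary_condition_bundle(
    waveform: Waveform,
    flow: Waveform,
    rc: WindkesselRC,
    inlet_area_mm2: float,
) -> dict:
    """Solver-ready boundary-condition export block."""
    from .meshing import SOLVER_EXPORT_BLOCK

    return {
        "inlet": {
            "profile": "parabolic",
            "phase_type": waveform.phase_type,
            "psv_cm_s": waveform.psv,
            "mdv_cm_s": waveform.mdv,
            "period_s": waveform.period,
            "area_mm2": inlet_area_mm2,
            "mean_flow_ml_min": flow.mean_flow_ml_min,
        },
        "outlet": {"R_MPa_s_per_mm3": rc.R, "C_mm3_per_MPa": rc.C},
        "initial_pressure_mmHg": 80.0,
        "solver": SOLVER_EXPORT_BLOCK,
    }
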