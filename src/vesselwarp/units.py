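"""Unit conversions for the mm-s-MPa internal unit system.

All geometry is carried in millimetres, time in seconds and pressure in
megapascals, so that lumped outlet parameters take the units
MPa*s/mm^3 (resistance) and mm^3/MPa (capacitance).  Clinical
quantities (mmHg, cm/s, ml/min) are converted at the interfaces.
"""

from __future__ import annotations

# 1 mmHg = 133.322387415 Pa (conventional mercury column definition)
MMHG_PER_PA = 1.0 / 133.322387415

MPA_PER_MMHG = 133.322387415e-6
MMHG_PER_MPA = 1.0 / MPA_PER_MMHG

PA_PER_MPA = 1.0e6


def mmhg_to_mpa(p_mmhg: float) -> float:
    return p_mmhg * MPA_PER_MMHG


def mpa_to_mmhg(p_mpa: float) -> float:
    return p_mpa * MMHG_PER_MPA


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * 133.322387415


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa * MMHG_PER_PA


def cm_s_to_mm_s(v_cm_s: float) -> float:
    return v_cm_s * 10.0


def mm3_s_to_ml_min(q_mm3_s: float) -> float:
    # 1 ml = 1000 mm^3, 1 min = 60 s
    return q_mm3_s * 60.0 / 1000.0


def ml_min_to_mm3_s(q_ml_min: float) -> float:
    return q_ml_min * 1000.0 / 60.0


def mm2_to_cm2(a_mm2: float) -> float:
    return a_mm2 / 100.0
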