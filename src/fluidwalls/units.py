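"""Unit helpers.

All internal computation is SI (m, m^3, Pa, s, kg).  User-facing interfaces
(config files, CLI, exports) use the bench units of open microfluidics:
mm for chamber dimensions, um for conduit/pixel dimensions, ul for volumes,
degrees for contact angles, hours/days for protocol schedules.
"""

UL_PER_M3 = 1e9
M3_PER_UL = 1e-9

S_PER_H = 3600.0
S_PER_DAY = 86400.0


def ul_to_m3(v_ul: float) -> float:
    return v_ul * M3_PER_UL


def m3_to_ul(v_m3: float) -> float:
    return v_m3 * UL_PER_M3


def mm_to_m(x_mm: float) -> float:
    return x_mm * 1e-3


def m_to_mm(x_m: float) -> float:
    return x_m * 1e3


def um_to_m(x_um: float) -> float:
    return x_um * 1e-6


def m_to_um(x_m: float) -> float:
    return x_m * 1e6


def h_to_s(t_h: float) -> float:
    return t_h * S_PER_H


def days_to_s(t_d: float) -> float:
    return t_d * S_PER_DAY
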