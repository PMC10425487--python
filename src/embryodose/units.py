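"""Unit conversions between the user-facing mm/hour frame and the internal cm/second frame.

All physical computation inside the package runs in cm, seconds and molar
concentration; the public API (profiles, placements, growth models) speaks
mm and hours because that is how the experiments are described.  Every
conversion goes through this module so there is a single place to audit.
"""

MM_PER_CM = 10.0
S_PER_H = 3600.0
UL_PER_CM3 = 1000.0  # 1 cm^3 = 1 mL = 1000 uL
L_PER_CM3 = 1e-3


def mm_to_cm(x_mm: float) -> float:
    return x_mm / MM_PER_CM


def cm_to_mm(x_cm: float) -> float:
    return x_cm * MM_PER_CM


def h_to_s(t_h: float) -> float:
    return t_h * S_PER_H


def s_to_h(t_s: float) -> float:
    return t_s / S_PER_H


def ul_to_cm3(v_ul: float) -> float:
    return v_ul / UL_PER_CM3


def cm3_to_liters(v_cm3: float) -> float:
    return v_cm3 * L_PER_CM3
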