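"""Unit conversions used at module interfaces.

SI units are used internally everywhere (m, s, kg, Pa). Clinical quantities
(thresholds, Windkessel parameters) are stated in mmHg and ml and converted
at the boundaries of the solver.
"""

#: Pa per mmHg
MMHG = 133.322

#: m^3 per ml
ML = 1e-6


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG
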