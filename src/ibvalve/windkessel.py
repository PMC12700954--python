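"""Three-element (RCR) Windkessel outlet model.

Proximal resistance R1 in series with the parallel pair of distal resistance
R2 and compliance C. With outlet flow Q (positive outward) the compartment
pressure p_c obeys

    C dp_c/dt = Q - p_c / R2,        P_out = p_c + R1 Q.

Clinical units are used throughout this module (mmHg, ml, s); the solver
converts at its boundary. The ODE is integrated with implicit Euler, which is
unconditionally stable at any solver time step and first-order accurate; its
steady state is exactly P_out = Q (R1 + R2) and its relaxation from rest is
the exponential with time constant R2*C.

Default parameters are the patient-scale values R1 = 0.072 mmHg*s/ml,
R2 = 1.40 mmHg*s/ml, C = 0.88 ml/mmHg (time constant R2*C = 1.232 s).
Phantom-scale runs rescale the resistances to the phantom's flow while
keeping this time constant; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class WindkesselState:
    r1: float = 0.072  # mmHg*s/ml
    r2: float = 1.40  # mmHg*s/ml
    c: float = 0.88  # ml/mmHg
    p_c: float = 80.0  # compartment pressure, mmHg

    def __post_init__(self):
        if min(self.r1, self.r2, self.c) <= 0:
            raise ValueError("R1, R2, C must be positive")
        if not np.isfinite(self.p_c):
            raise ValueError("p_c must be finite")

    @property
    def time_constant(self) -> float:
        """Relaxation time constant R2*C [s]."""
        return self.r2 * self.c


def windkessel_update(wk: WindkesselState, q_ml_s: float, dt: float) -> float:
    """Advance one step with outlet flow Q [ml/s]; returns P_out [mmHg].

    Implicit Euler: p_c <- (p_c + dt*Q/C) / (1 + dt/(R2*C)).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(q_ml_s):
        raise ValueError("Q must be finite")
    wk.p_c = (wk.p_c + dt * q_ml_s / wk.c) / (1.0 + dt / (wk.r2 * wk.c))
    return wk.p_c + wk.r1 * q_ml_s
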