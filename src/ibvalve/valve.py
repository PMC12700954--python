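"""Reduced-order prosthetic valve: rigid housing + parameterized leaflets.

Leaflet kinematics are collapsed to a single state L in [0, 1]: L = 0 is the
fully closed configuration, L = 1 fully open, and intermediate positions are
the per-point linear blend of the two (the closed and open point sets are in
one-to-one correspondence). L is driven by the transvalvular pressure
gradient: it opens at a fixed rate R_leaf while the gradient exceeds P_open,
closes at the same rate while the gradient is below -P_close, and holds
otherwise (the thresholds exist to prevent instantaneous switching at zero
gradient, not to model friction or inertia). A full transition therefore
takes 1/R_leaf seconds; the default R_leaf = 20 1/s gives 50 ms opening and
closing times, within the 25-75 ms range reported for prosthetic leaflets
in vivo. Leaflet inertance and fluttering are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .motion import RigidTransform
from .structure import LagrangianStructure


@dataclass
class ValveModel:
    housing: LagrangianStructure
    leaflets: list  # list[LagrangianStructure], reference = closed config
    leaflets_closed: list  # list[(n, 2)] positions at L = 0
    leaflets_open: list  # list[(n, 2)] positions at L = 1
    annulus_center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    annulus_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    annulus_diameter: float = 0.0
    L: float = 0.0
    R_leaf: float = 20.0  # 1/s
    P_open_mmhg: float = 1.0
    P_close_mmhg: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.L <= 1.0:
            raise ValueError("L must lie in [0, 1]")
        if self.R_leaf <= 0:
            raise ValueError("R_leaf must be positive")
        if self.P_open_mmhg <= 0 or self.P_close_mmhg <= 0:
            raise ValueError("opening/closing thresholds must be positive")
        for k, (cl, op) in enumerate(zip(self.leaflets_closed, self.leaflets_open)):
            if np.asarray(cl).shape != np.asarray(op).shape:
                raise ValueError(
                    f"leaflet {k}: closed and open configurations must have "
                    "identical point counts and ordering"
                )

    @property
    def structures(self) -> list:
        return [self.housing] + list(self.leaflets)

    def transformed(self, tr: RigidTransform) -> "ValveModel":
        """Apply a rigid map to the whole valve (housing, both leaflet
        configurations, annulus frame). Pairwise distances are preserved."""
        housing = self.housing.copy()
        housing.X = tr.apply(housing.X)
        housing.chi = tr.apply(housing.chi)
        leaflets = []
        for lf in self.leaflets:
            lf2 = lf.copy()
            lf2.X = tr.apply(lf2.X)
            lf2.chi = tr.apply(lf2.chi)
            leaflets.append(lf2)
        R = tr.rotation_matrix
        return replace(
            self,
            housing=housing,
            leaflets=leaflets,
            leaflets_closed=[tr.apply(c) for c in self.leaflets_closed],
            leaflets_open=[tr.apply(o) for o in self.leaflets_open],
            annulus_center=tr.apply(self.annulus_center[None])[0],
            annulus_axis=R @ self.annulus_axis,
        )


def leaflet_positions(
    valve: ValveModel, L: float, transform: RigidTransform | None = None
) -> list:
    """Leaflet point positions at opening state L, in the current valve frame.

    Per point: (1 - L) * closed + L * open, then the rigid valve-motion
    transform (if any) is applied. Point paths in the valve frame are
    straight segments.
    """
    if not 0.0 <= L <= 1.0:
        raise ValueError(f"L = {L} outside [0, 1]")
    out = []
    for cl, op in zip(valve.leaflets_closed, valve.leaflets_open):
        pos = (1.0 - L) * np.asarray(cl) + L * np.asarray(op)
        if transform is not None:
            pos = transform.apply(pos)
        out.append(pos)
    return out


def update_leaflet_state(valve: ValveModel, dp_mmhg: float, dt: float) -> float:
    """Advance L one step under transvalvular gradient dp (LV minus aorta).

    dp > P_open opens, dp < -P_close closes, the dead band in between holds
    the current state; |dL| per step is exactly R_leaf * dt except at the
    clamps. Returns the new L (also stored on the valve).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(dp_mmhg):
        raise ValueError("pressure gradient must be finite")
    L = valve.L
    if dp_mmhg > valve.P_open_mmhg:
        L = min(1.0, L + valve.R_leaf * dt)
    elif dp_mmhg < -valve.P_close_mmhg:
        L = max(0.0, L - valve.R_leaf * dt)
    valve.L = L
    return L
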