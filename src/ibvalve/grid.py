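"""Staggered (MAC) Cartesian grid and the Eulerian flow state.

Velocity components live on cell faces (u on vertical faces, v on horizontal
faces) and pressure at cell centers, which gives a tight discrete divergence
and a compatible five-point pressure Poisson operator. Grid indices are
0-based and cell (i, j) spans [x0 + i*h, x0 + (i+1)*h) x [y0 + j*h, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class EulerianGrid:
    nx: int
    ny: int
    h: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.nx < 8 or self.ny < 8:
            raise ValueError("need at least 8 cells per direction")

    @property
    def extent(self):
        """(x0, x1, y0, y1) of the domain."""
        return (self.x0, self.x0 + self.nx * self.h, self.y0, self.y0 + self.ny * self.h)

    # --- staggered layouts -------------------------------------------------
    @property
    def u_shape(self):
        return (self.nx + 1, self.ny)

    @property
    def v_shape(self):
        return (self.nx, self.ny + 1)

    @property
    def p_shape(self):
        return (self.nx, self.ny)

    @property
    def u_origin(self):
        """Physical position of u-node (0, 0)."""
        return (self.x0, self.y0 + 0.5 * self.h)

    @property
    def v_origin(self):
        return (self.x0 + 0.5 * self.h, self.y0)

    @property
    def p_origin(self):
        return (self.x0 + 0.5 * self.h, self.y0 + 0.5 * self.h)

    def cell_centers(self):
        """Meshgrid (X, Y) of cell-center coordinates, shape (nx, ny)."""
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.h
        y = self.y0 + (np.arange(self.ny) + 0.5) * self.h
        return np.meshgrid(x, y, indexing="ij")

    def divergence(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Discrete divergence at cell centers."""
        return (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / self.h


@dataclass
class FlowState:
    """Velocity/pressure fields plus fluid properties.

    Defaults mimic blood: rho = 1060 kg/m^3, mu = 3.5e-3 Pa*s.
    """

    grid: EulerianGrid
    rho: float = 1060.0
    mu: float = 3.5e-3
    t: float = 0.0
    u: np.ndarray = field(default=None)
    v: np.ndarray = field(default=None)
    p: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.u is None:
            self.u = np.zeros(self.grid.u_shape)
        if self.v is None:
            self.v = np.zeros(self.grid.v_shape)
        if self.p is None:
            self.p = np.zeros(self.grid.p_shape)

    @property
    def nu(self) -> float:
        return self.mu / self.rho

    def max_speed(self) -> float:
        return max(float(np.max(np.abs(self.u))), float(np.max(np.abs(self.v))))

    def check_finite(self) -> None:
        for name, f in (("u", self.u), ("v", self.v), ("p", self.p)):
            if not np.all(np.isfinite(f)):
                raise FloatingPointError(
                    f"non-finite values in field {name} at t = {self.t:.6g} s"
                )
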