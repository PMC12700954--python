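"""Hemodynamic evaluation: transvalvular pressure drop, viscous power and
energy loss, flow rate, and cycle bookkeeping.

The pressure drop is the difference between the mean pressures sampled over
two 20-point clouds, one on the ventricular side and one on the aortic side
of the valve. Viscous dissipation is integrated over the fluid interior:

    P_loss = int_V 2 mu S : S dV,    E_loss = int_T P_loss dt,

with S the rate-of-deformation tensor (symmetric velocity gradient). In the
2D reduction both carry an implicit unit depth (1 m): P_loss is W per metre
of depth and E_loss J per metre of depth. Reported metrics come from the
second simulated cycle by default; the first is discarded as initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path

from .grid import EulerianGrid
from .units import pa_to_mmhg


# ---------------------------------------------------------------------------
# sample clouds
# ---------------------------------------------------------------------------
CLOUD_SIZE = 20


@dataclass(frozen=True)
class SampleClouds:
    """Two 20-point pressure sampling clouds on opposite sides of the valve."""

    lv: np.ndarray  # (20, 2) ventricular side
    aorta: np.ndarray  # (20, 2) aortic side

    def __post_init__(self):
        for name, c in (("lv", self.lv), ("aorta", self.aorta)):
            if np.asarray(c).shape != (CLOUD_SIZE, 2):
                raise ValueError(f"{name} cloud must contain exactly {CLOUD_SIZE} points")


def disc_cloud(center, radius: float, n: int = CLOUD_SIZE) -> np.ndarray:
    """Deterministic n-point disc: center + rings at radius/2 and radius."""
    cx, cy = center
    pts = [(cx, cy)]
    for r, m in ((0.5 * radius, (n - 1) // 3), (radius, n - 1 - (n - 1) // 3)):
        ang = 2.0 * np.pi * np.arange(m) / m
        pts.extend(zip(cx + r * np.cos(ang), cy + r * np.sin(ang)))
    return np.array(pts[:n])


def _bilinear_centers(field: np.ndarray, points: np.ndarray, grid: EulerianGrid) -> np.ndarray:
    """Bilinear interpolation of a cell-centered field at physical points."""
    gx = (points[:, 0] - grid.x0) / grid.h - 0.5
    gy = (points[:, 1] - grid.y0) / grid.h - 0.5
    i0 = np.clip(np.floor(gx).astype(int), 0, grid.nx - 2)
    j0 = np.clip(np.floor(gy).astype(int), 0, grid.ny - 2)
    fx = gx - i0
    fy = gy - j0
    return (
        field[i0, j0] * (1 - fx) * (1 - fy)
        + field[i0 + 1, j0] * fx * (1 - fy)
        + field[i0, j0 + 1] * (1 - fx) * fy
        + field[i0 + 1, j0 + 1] * fx * fy
    )


def pressure_drop(
    p: np.ndarray,
    clouds: SampleClouds,
    grid: EulerianGrid,
    mask: np.ndarray | None = None,
) -> float:
    """Delta p = mean(p at LV cloud) - mean(p at aorta cloud), in mmHg."""
    if mask is not None:
        for name, c in (("lv", clouds.lv), ("aorta", clouds.aorta)):
            i = np.clip(((c[:, 0] - grid.x0) / grid.h).astype(int), 0, grid.nx - 1)
            j = np.clip(((c[:, 1] - grid.y0) / grid.h).astype(int), 0, grid.ny - 1)
            inside = mask[i, j]
            if not np.all(inside):
                k = int(np.argmin(inside))
                raise ValueError(f"{name} cloud point {k} at {c[k]} lies outside the fluid")
    p_lv = _bilinear_centers(p, clouds.lv, grid).mean()
    p_ao = _bilinear_centers(p, clouds.aorta, grid).mean()
    return pa_to_mmhg(p_lv - p_ao)


# ---------------------------------------------------------------------------
# viscous dissipation
# ---------------------------------------------------------------------------
def rate_of_deformation(u: np.ndarray, v: np.ndarray, grid: EulerianGrid):
    """S = (grad u + grad u^T)/2 at cell centers; returns (S11, S22, S12)."""
    h = grid.h
    s11 = (u[1:, :] - u[:-1, :]) / h
    s22 = (v[:, 1:] - v[:, :-1]) / h
    uc = 0.5 * (u[1:, :] + u[:-1, :])
    vc = 0.5 * (v[:, 1:] + v[:, :-1])
    dudy = np.gradient(uc, h, axis=1)
    dvdx = np.gradient(vc, h, axis=0)
    s12 = 0.5 * (dudy + dvdx)
    return s11, s22, s12


def power_loss(u: np.ndarray, v: np.ndarray, mask: np.ndarray, mu: float, grid: EulerianGrid) -> float:
    """P_loss = sum over masked cells of 2 mu S:S h^2 [W per unit depth]."""
    if not np.any(mask):
        raise ValueError("empty integration mask")
    s11, s22, s12 = rate_of_deformation(u, v, grid)
    density = 2.0 * mu * (s11**2 + s22**2 + 2.0 * s12**2)
    return float(np.sum(density[mask]) * grid.h**2)


def energy_loss(times: np.ndarray, p_loss: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoidal integral of P_loss over [t0, t1] (one cardiac cycle)."""
    times = np.asarray(times, dtype=float)
    p_loss = np.asarray(p_loss, dtype=float)
    eps = 1e-9 * max(t1 - t0, 1.0)
    sel = (times >= t0 - eps) & (times <= t1 + eps)
    if sel.sum() < 2 or times[sel][0] > t0 + 0.05 * (t1 - t0) or times[sel][-1] < t1 - 0.05 * (t1 - t0):
        raise ValueError(f"cycle [{t0}, {t1}] not fully covered by the series")
    return float(np.trapezoid(p_loss[sel], times[sel]))


# ---------------------------------------------------------------------------
# interior mask
# ---------------------------------------------------------------------------
def interior_mask(
    boundary_vertices: np.ndarray, grid: EulerianGrid, decimate: int = 1
) -> np.ndarray:
    """Boolean (nx, ny) mask of cell centers inside a closed polygon.

    The polygon is the wall polyline closed by the outlet (and any inflow)
    segments; classification is even-odd ray crossing. `decimate` keeps every
    k-th vertex to bound the cost on dense polylines.
    """
    verts = np.asarray(boundary_vertices, dtype=float)
    if len(verts) < 3:
        raise ValueError("boundary must have at least 3 vertices")
    if decimate > 1:
        verts = verts[::decimate]
    X, Y = grid.cell_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    # matplotlib's closed Path treats the final vertex as the CLOSEPOLY
    # marker, so the loop must be closed explicitly
    path = Path(np.vstack([verts, verts[:1]]), closed=True)
    return path.contains_points(pts).reshape(grid.nx, grid.ny)


def structure_band_mask(points: np.ndarray, grid: EulerianGrid, half_width: float) -> np.ndarray:
    """Cells whose center lies within `half_width` of any structure point.

    Used to exclude the smeared penalty layer around the housing and leaflets
    from the dissipation integral.
    """
    mask = np.zeros((grid.nx, grid.ny), dtype=bool)
    r = int(np.ceil(half_width / grid.h)) + 1
    gx = (points[:, 0] - grid.x0) / grid.h - 0.5
    gy = (points[:, 1] - grid.y0) / grid.h - 0.5
    i0 = np.round(gx).astype(int)
    j0 = np.round(gy).astype(int)
    X, Y = grid.cell_centers()
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            i = np.clip(i0 + di, 0, grid.nx - 1)
            j = np.clip(j0 + dj, 0, grid.ny - 1)
            d2 = (X[i, j] - points[:, 0]) ** 2 + (Y[i, j] - points[:, 1]) ** 2
            hit = d2 <= half_width**2
            mask[i[hit], j[hit]] = True
    return mask


# ---------------------------------------------------------------------------
# time series container
# ---------------------------------------------------------------------------
@dataclass
class MetricsSeries:
    """Sampled hemodynamic series for one simulation run."""

    period: float
    times: list = field(default_factory=list)
    dp_mmhg: list = field(default_factory=list)
    q_ml_s: list = field(default_factory=list)
    p_loss: list = field(default_factory=list)
    leaflet_state: list = field(default_factory=list)
    cfl: list = field(default_factory=list)
    p_out_mmhg: list = field(default_factory=list)

    def append(self, t, dp, q, ploss, L, cfl, p_out):
        self.times.append(float(t))
        self.dp_mmhg.append(float(dp))
        self.q_ml_s.append(float(q))
        self.p_loss.append(float(ploss))
        self.leaflet_state.append(float(L))
        self.cfl.append(float(cfl))
        self.p_out_mmhg.append(float(p_out))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.times,
                "dp_mmhg": self.dp_mmhg,
                "q_ml_s": self.q_ml_s,
                "p_loss_w_per_m": self.p_loss,
                "leaflet_L": self.leaflet_state,
                "cfl": self.cfl,
                "p_out_mmhg": self.p_out_mmhg,
            }
        )

    def cycle_window(self, cycle: int):
        return cycle * self.period, (cycle + 1) * self.period

    def cycle_selection(self, cycle: int) -> np.ndarray:
        t = np.asarray(self.times)
        t0, t1 = self.cycle_window(cycle)
        eps = 1e-9 * self.period
        return (t >= t0 - eps) & (t <= t1 + eps)

    def peak_dp(self, cycle: int = 1) -> float:
        sel = self.cycle_selection(cycle)
        if not np.any(sel):
            raise ValueError(f"cycle {cycle} not simulated")
        return float(np.max(np.asarray(self.dp_mmhg)[sel]))

    def energy_loss(self, cycle: int = 1) -> float:
        t0, t1 = self.cycle_window(cycle)
        return energy_loss(np.asarray(self.times), np.asarray(self.p_loss), t0, t1)

    def ejected_volume_ml(self, cycle: int = 1) -> float:
        """Cycle-integrated forward outlet volume [ml per unit depth]."""
        sel = self.cycle_selection(cycle)
        t = np.asarray(self.times)[sel]
        q = np.clip(np.asarray(self.q_ml_s)[sel], 0.0, None)
        return float(np.trapezoid(q, t))
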