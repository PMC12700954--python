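"""Solution-verification utilities: grid convergence on an analytic channel
flow, penalty-parameter calibration, and leakage measurement.

The plane-Poiseuille channel (body-force driven, no-slip walls on the domain
boundary, open ends) has the exact steady profile u(y) = G y (H - y) / (2 mu),
which serves as the oracle for the spatial-convergence study and for the
dissipation checks. The penalty variants replace the resolved walls with
immersed penalty walls to quantify tracking and leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import EulerianGrid, FlowState
from .solver import BoundaryConditions, PressureSolver, advance, stable_dt
from .structure import polyline, resample_polyline


# ---------------------------------------------------------------------------
# plane Poiseuille with resolved walls
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PoiseuilleCase:
    """Body-force-driven channel: gap H across y, no-slip top/bottom walls on
    the domain boundary, zero-pressure open ends."""

    H: float = 1.0  # m
    G: float = 1.0  # N/m^3 body force
    mu: float = 0.1  # Pa*s
    rho: float = 1.0  # kg/m^3
    aspect: float = 0.25  # domain length = aspect * H

    def exact_profile(self, y: np.ndarray) -> np.ndarray:
        return self.G / (2.0 * self.mu) * y * (self.H - y)

    @property
    def u_max(self) -> float:
        return self.G * self.H**2 / (8.0 * self.mu)


def run_poiseuille(case: PoiseuilleCase, ny: int, n_time_constants: float = 16.0):
    """March the channel to steady state; returns (state, rel. L2 error)."""
    h = case.H / ny
    nx = max(8, int(round(case.aspect * case.H / h)))
    grid = EulerianGrid(nx, ny, h)
    bc = BoundaryConditions(bottom="noslip", top="noslip")
    psolver = PressureSolver(grid, bc)
    state = FlowState(grid, rho=case.rho, mu=case.mu)
    nu = case.mu / case.rho
    dt = 0.6 * h * h / (4.0 * nu)
    t_end = n_time_constants * case.H**2 / (nu * np.pi**2)
    for _ in range(int(np.ceil(t_end / dt))):
        advance(state, [], dt, bc, psolver, body_force=(case.G / case.rho, 0.0))
    y = (np.arange(ny) + 0.5) * h
    exact = case.exact_profile(y)
    num = state.u[nx // 2, :]
    err = float(np.linalg.norm(num - exact) / np.linalg.norm(exact))
    return state, err


def grid_convergence(case: PoiseuilleCase | None = None, ny_values=(16, 32, 64)) -> pd.DataFrame:
    """L2 velocity error on successively refined grids + observed order.

    Returns a DataFrame with one row per grid; the observed order between
    refinements k and k+1 is log2(err_k / err_{k+1}).
    """
    case = case or PoiseuilleCase()
    rows = []
    prev = None
    for ny in ny_values:
        _, err = run_poiseuille(case, ny)
        order = np.nan if prev is None else float(np.log2(prev / err))
        rows.append({"ny": ny, "h": case.H / ny, "l2_error": err, "observed_order": order})
        prev = err
    df = pd.DataFrame(rows)
    errs = df["l2_error"].to_numpy()
    df.attrs["monotone"] = bool(np.all(np.diff(errs) < 0))
    return df


# ---------------------------------------------------------------------------
# penalty walls: tracking and leakage
# ---------------------------------------------------------------------------
#: effective hydrodynamic wall position of the quadratic-B-spline penalty
#: layer, in cells inside the structure line. Measured by fitting the roots
#: of the steady channel profile at several resolutions (0.378 +- 0.001 h,
#: resolution-independent); a kernel constant analogous to the wall half-link
#: offset of lattice-Boltzmann bounce-back walls.
WALL_OFFSET_H = 0.378


def _penalty_channel(ny: int, gap_fraction: float = 0.5, wall_offset_h: float = WALL_OFFSET_H):
    """Domain with an immersed horizontal channel of the given gap, pressure
    driven along x. The wall structure lines are placed `wall_offset_h` cells
    outside the nominal gap so the effective no-slip planes land on it."""
    H = 1.0
    h = H / ny
    nx = 2 * ny
    grid = EulerianGrid(nx, ny, h)
    y0 = 0.5 * H * (1 - gap_fraction)
    y1 = 0.5 * H * (1 + gap_fraction)
    margin = 2 * h
    pts_bot = resample_polyline(
        np.array([[margin, y0 - wall_offset_h * h], [nx * h - margin, y0 - wall_offset_h * h]]),
        0.5 * h,
    )
    pts_top = resample_polyline(
        np.array([[margin, y1 + wall_offset_h * h], [nx * h - margin, y1 + wall_offset_h * h]]),
        0.5 * h,
    )
    return grid, y0, y1, pts_bot, pts_top


def penalty_channel_flow(
    ny: int = 32,
    kappa: float = 1e6,
    eta: float | None = None,
    dp: float = 1.0,
    t_end: float = 4.0,
    barrier: bool = False,
    rho: float = 1.0,
    mu: float = 0.05,
    dt_fixed: float | None = None,
):
    """Pressure-driven flow between two static penalty walls.

    The left boundary carries pressure `dp`, the right 0 (via an outlet band
    spanning the gap with reversed sign convention: here we simply drive with
    a uniform body force equivalent, see below). With `barrier=True` a
    transverse penalty wall blocks the gap mid-channel; the returned flux
    then measures leakage through a closed wall.

    Returns dict with the mid-channel flux, the analytic open-channel flux,
    the max tracking error, and the state.
    """
    grid, y0, y1, pts_bot, pts_top = _penalty_channel(ny)
    h = grid.h
    gap = y1 - y0
    L = grid.nx * h
    G = dp / L  # pressure gradient as body force
    structures = [
        polyline(pts_bot, role="wall", kappa=kappa, name="wall_bot"),
        polyline(pts_top, role="wall", kappa=kappa, name="wall_top"),
    ]
    if barrier:
        xb = 0.5 * L
        pts_b = resample_polyline(np.array([[xb, y0], [xb, y1]]), 0.5 * h)
        structures.append(polyline(pts_b, role="wall", kappa=kappa, name="barrier"))
    nu = mu / rho
    dt = stable_dt(grid, structures, rho, nu, u_max=0.0, safety=0.7)
    dt = min(dt, 0.6 * h * h / (4.0 * nu))
    for s in structures:
        s.eta = eta if eta is not None else min(5e-4 * kappa, 0.7 * rho * h**2 / (np.max(s.weights) * dt))
    dt = min(dt, stable_dt(grid, structures, rho, nu, u_max=0.0, safety=0.7))
    if dt_fixed is not None:
        dt = dt_fixed  # caller-forced step (e.g. to probe the stability margin)
    bc = BoundaryConditions(bottom="noslip", top="noslip")
    psolver = PressureSolver(grid, bc)
    state = FlowState(grid, rho=rho, mu=mu)
    track = 0.0
    for _ in range(int(np.ceil(t_end / dt))):
        d = advance(state, structures, dt, bc, psolver, body_force=(G / rho, 0.0))
        track = max(track, max(d["tracking"].values()))
    i = grid.nx // 4 if barrier else grid.nx // 2
    j0 = int(round(y0 / h))
    j1 = int(round(y1 / h))
    flux = float(np.sum(state.u[i, j0:j1]) * h)
    q_open = G * gap**3 / (12.0 * mu)  # Poiseuille flux at this gradient
    return {
        "flux": flux,
        "open_flux": q_open,
        "tracking_error": track,
        "state": state,
        "dt": dt,
        "grid": grid,
    }


def tracking_vs_kappa(kappas, ny: int = 32, **kw) -> pd.DataFrame:
    """Max wall tracking error as kappa sweeps upward (decades)."""
    rows = []
    for k in kappas:
        try:
            r = penalty_channel_flow(ny=ny, kappa=k, **kw)
            rows.append(
                {"kappa": k, "tracking_error": r["tracking_error"], "stable": True,
                 "flux": r["flux"]}
            )
        except (RuntimeError, FloatingPointError):
            rows.append({"kappa": k, "tracking_error": np.nan, "stable": False,
                         "flux": np.nan})
    return pd.DataFrame(rows)


def leakage_fraction(ny: int = 32, kappa: float = 1e6, **kw) -> float:
    """Leakage through a closed transverse penalty wall, as a fraction of the
    open-channel flux under the same drive."""
    blocked = penalty_channel_flow(ny=ny, kappa=kappa, barrier=True, **kw)
    return abs(blocked["flux"]) / blocked["open_flux"]


def rleaf_sensitivity(
    r_leaf_values=(10.0, 20.0, 40.0),
    config=None,
    params=None,
) -> pd.DataFrame:
    """Baseline-scenario sensitivity to the leaflet opening/closing rate.

    Runs the baseline placement at each R_leaf [1/s] and reports the peak
    transvalvular pressure drop, cycle energy loss, and the measured
    closed-to-open transition duration (which should equal 1/R_leaf when the
    gradient stays above the opening threshold throughout the transition).
    """
    from .phantom import PhantomConfig, make_phantom
    from .simulation import RunParams, run_scenario

    rows = []
    for r in r_leaf_values:
        scene = make_phantom(config or PhantomConfig())
        scene.valve.R_leaf = float(r)
        res = run_scenario(scene, params or RunParams())
        durations = res.opening_durations()
        rows.append(
            {
                "r_leaf": float(r),
                "peak_dp_mmhg": res.peak_dp(),
                "e_loss_j_per_m": res.energy_loss(),
                "opening_duration_s": durations[-1] if durations else np.nan,
                "expected_duration_s": 1.0 / r,
            }
        )
    return pd.DataFrame(rows)


def calibrate_penalty(
    kappa_start: float = 1e4,
    n_decades: int = 5,
    ny: int = 32,
    target_fraction_h: float = 0.5,
    **kw,
) -> dict:
    """Geometric sweep over kappa (x10 steps, eta at the fixed ratio): the
    recommendation is the smallest kappa whose max tracking error is below
    `target_fraction_h` * h with no blow-up.

    Returns {'kappa': value or None, 'eta': value or None, 'report': DataFrame}.
    """
    kappas = kappa_start * 10.0 ** np.arange(n_decades)
    df = tracking_vs_kappa(kappas, ny=ny, **kw)
    h = 1.0 / ny
    df["target_met"] = df["stable"] & (df["tracking_error"] < target_fraction_h * h)
    ok = df[df["target_met"]]
    if len(ok) == 0:
        return {"kappa": None, "eta": None, "report": df}
    kappa = float(ok["kappa"].iloc[0])
    return {"kappa": kappa, "eta": 5e-4 * kappa, "report": df}
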