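"""Scenario driver: couples phantom motion, valve dynamics, the IB solver,
the Windkessel outlet and the metrics pipeline into a multi-cycle run.

Each time step: (1) wall targets from the keyframe interpolant; (2) valve
rigid-body targets from the landing-zone Horn fit; (3) leaflet targets from
the open/closed blend at the current state L; (4) one IB solver step with the
Windkessel pressure on the outlet band; (5) outlet flow -> Windkessel update;
(6) transvalvular cloud pressure drop -> leaflet state update for both the
aortic and the inflow valve. Metrics are sampled on a fixed step cadence and
reported from the second cycle (the first is discarded as initialization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import FlowState
from .metrics import (
    MetricsSeries,
    interior_mask,
    power_loss,
    pressure_drop,
    structure_band_mask,
)
from .motion import RigidTransform, extract_landing_zone, valve_rigid_motion
from .phantom import Placement, PhantomScene, make_phantom, shoelace_area
from .solver import BoundaryConditions, PressureSolver, advance, cfl_number, stable_dt
from .units import ML, mmhg_to_pa
from .valve import leaflet_positions, update_leaflet_state
from .windkessel import WindkesselState, windkessel_update


@dataclass
class RunParams:
    """Fluid, numerical and outlet parameters for phantom scenario runs.

    The Windkessel defaults are the patient-scale values rescaled to the 2D
    phantom's flow (stroke "volume" ~960 ml per metre of depth): the R1/R2
    ratio and the relaxation time constant R2*C = 1.232 s are preserved and
    the total resistance is chosen for a desk-scale mean outlet pressure of
    roughly 8 mmHg, a load the penalty walls hold tightly at the default
    time step. Penalty parameters default to an automatic choice at a fixed
    fraction of the explicit stability limit for the selected time step,
    with the damping-to-stiffness ratio eta/kappa = 5e-4 s.
    """

    rho: float = 1060.0  # kg/m^3
    mu: float = 0.2  # Pa*s; desk-scale working fluid (see docs/methods.md)
    cfl_target: float = 0.2
    dt_fixed: float | None = None  # s; None = automatic
    u_est: float = 1.0  # m/s velocity scale for the automatic dt
    n_cycles: int = 3
    kappa: float | None = None  # Pa/m; None = automatic
    eta: float | None = None  # Pa*s/m; None = ratio * kappa
    eta_kappa_ratio: float = 5e-4  # s (5e3 / 1e7, the patient-scale ratio)
    penalty_safety: float = 0.8
    wk_r1: float = 0.000408  # mmHg*s/ml
    wk_r2: float = 0.00793  # mmHg*s/ml
    wk_c: float = 155.4  # ml/mmHg
    wk_p0: float = 6.6  # mmHg; limit-cycle end-diastolic value
    sample_every: int = 10  # steps between metric samples
    mask_every: int = 5  # samples between interior-mask rebuilds
    mask_decimate: int = 6
    weights_every: int = 5  # steps between quadrature-weight updates
    report_cycle: int = 1  # 0-based; 1 = second cycle
    startup_ramp: float = 0.05  # s; outlet pressure soft-start (cycle 1 is discarded)
    seed: int = 0

    def resolve_dt(self, grid, nu: float) -> float:
        if self.dt_fixed is not None:
            return self.dt_fixed
        dt = self.cfl_target * grid.h / self.u_est
        if nu > 0:
            dt = min(dt, 0.7 * grid.h**2 / (4.0 * nu))
        return dt

    def resolve_penalty(self, grid, dt: float, w_max: float):
        if self.kappa is not None:
            kappa = self.kappa
        else:
            kappa = self.penalty_safety**2 * self.rho * grid.h**2 / (w_max * dt**2)
        if self.eta is not None:
            eta = self.eta
        else:
            eta = min(self.eta_kappa_ratio * kappa, 0.7 * self.rho * grid.h**2 / (w_max * dt))
        return kappa, eta


@dataclass
class ScenarioResult:
    label: str
    metrics: MetricsSeries
    scene: PhantomScene
    state: FlowState
    dt: float
    kappa: float
    eta: float
    max_tracking_error: float
    report_cycle: int
    valve_events: list = field(default_factory=list)  # (t, event-name)

    def opening_durations(self) -> list:
        """Durations [s] of complete closed->open leaflet transitions."""
        out = []
        t_start = None
        for t, ev in self.valve_events:
            if ev == "open_start":
                t_start = t
            elif ev == "open_end" and t_start is not None:
                out.append(t - t_start)
                t_start = None
        return out

    def peak_dp(self, cycle: int | None = None) -> float:
        return self.metrics.peak_dp(self.report_cycle if cycle is None else cycle)

    def energy_loss(self, cycle: int | None = None) -> float:
        return self.metrics.energy_loss(self.report_cycle if cycle is None else cycle)

    def keyframe_stroke_area_ml(self) -> float:
        """Chamber area change over the keyframes [ml per unit depth]."""
        kf = self.scene.keyframes
        areas = [
            shoelace_area(self.scene.chamber_polygon(kf.displacements[:, k, :]))
            for k in range(self.scene.config.n_phases)
        ]
        return (max(areas) - min(areas)) / ML  # m^2 x unit depth -> ml

    def mass_consistency(self, cycle: int | None = None) -> float:
        """Ejected outlet volume / keyframe stroke area (1.0 = exact)."""
        c = self.report_cycle if cycle is None else cycle
        return self.metrics.ejected_volume_ml(c) / self.keyframe_stroke_area_ml()

    def cycle_agreement(self) -> dict:
        """Relative change of peak dp and E_loss between cycles 2 and 3."""
        out = {}
        for name, fn in (("peak_dp", self.peak_dp), ("e_loss", self.energy_loss)):
            a, b = fn(1), fn(2)
            out[name] = abs(b - a) / max(abs(a), 1e-30)
        return out

    def summary(self) -> dict:
        return {
            "label": self.label,
            "peak_dp_mmhg": self.peak_dp(),
            "e_loss_j_per_m": self.energy_loss(),
            "reported_cycle": self.report_cycle + 1,
            "mass_consistency": self.mass_consistency(),
            "max_tracking_error_m": self.max_tracking_error,
            "dt_s": self.dt,
            "kappa": self.kappa,
            "eta": self.eta,
        }


class _ValveDriver:
    """Tracks one valve's rigid motion + leaflet blend targets."""

    def __init__(self, valve, scene, rigid: bool, clouds, dt: float):
        self.valve = valve
        self.clouds = clouds
        self.rigid = rigid
        self.dt = dt
        if rigid:
            self.lz = extract_landing_zone(
                scene.wall, valve.housing, threshold=0.6 * scene.grid.h
            )
        self._prev = {id(s): s.X.copy() for s in valve.structures}

    def transform_at(self, kf, t: float) -> RigidTransform:
        if not self.rigid:
            return RigidTransform.identity()
        return valve_rigid_motion(kf, self.lz, t)

    def set_targets(self, kf, t: float) -> None:
        tr = self.transform_at(kf, t)
        housing = self.valve.housing
        target = tr.apply(housing.X)
        housing.D = target - housing.X
        housing.U_s = (target - self._prev[id(housing)]) / self.dt
        self._prev[id(housing)] = target
        blends = leaflet_positions(self.valve, self.valve.L)
        for lf, pos in zip(self.valve.leaflets, blends):
            target = tr.apply(pos)
            lf.D = target - lf.X
            lf.U_s = (target - self._prev[id(lf)]) / self.dt
            self._prev[id(lf)] = target

    def update_state(self, p, grid, dt: float) -> float:
        dp = pressure_drop(p, self.clouds, grid)
        update_leaflet_state(self.valve, dp, dt)
        return dp


def run_scenario(
    scene: PhantomScene,
    params: RunParams | None = None,
    placement: Placement | None = None,
    snapshot_callback=None,
) -> ScenarioResult:
    """Simulate one placement scenario for params.n_cycles cardiac cycles."""
    from .phantom import implant_valve

    params = params or RunParams()
    if placement is not None:
        implant_valve(scene.valve, scene, placement)
    cfg = scene.config
    grid = scene.grid
    nu = params.mu / params.rho
    dt = params.resolve_dt(grid, nu)

    structures = [scene.wall] + scene.valve.structures + scene.inflow_valve.structures
    if scene.baffles is not None:
        structures.append(scene.baffles)
    w_max = max(float(np.max(s.weights)) for s in structures)
    kappa, eta = params.resolve_penalty(grid, dt, w_max)
    for s in structures:
        s.kappa = kappa * s.penalty_scale
        s.eta = eta * s.penalty_scale
    # sanity: requested dt must respect every explicit stability limit
    dt_lim = stable_dt(grid, structures, params.rho, nu, params.u_est,
                       params.cfl_target, safety=1.0)
    dt = min(dt, dt_lim)

    state = FlowState(grid, rho=params.rho, mu=params.mu)
    # left boundary open (zero-pressure drain/reservoir); top and bottom are
    # solid so no short-circuit path connects the pressurized outlet to the
    # zero-pressure far field around the wall ends
    bc = BoundaryConditions(
        bottom="noslip",
        top="noslip",
        outlet=scene.outlet,
        outlet_wall=True,
        outlet_wall_margin=5,
    )
    psolver = PressureSolver(grid, bc)
    wk = WindkesselState(params.wk_r1, params.wk_r2, params.wk_c, params.wk_p0)
    p_out_mmhg = wk.p_c

    kf = scene.keyframes
    aortic = _ValveDriver(scene.valve, scene, rigid=True, clouds=scene.clouds, dt=dt)
    inflow = _ValveDriver(
        scene.inflow_valve, scene, rigid=False, clouds=scene.inflow_clouds, dt=dt
    )

    series = MetricsSeries(period=cfg.period)
    valve_events = []
    n_steps = int(round(params.n_cycles * cfg.period / dt))
    mask = None
    max_track = 0.0
    lo, hi = scene.outlet.lo, scene.outlet.hi
    sample_count = 0
    dp = 0.0

    for step in range(n_steps):
        t = state.t
        scene.wall.D = kf.displacement(t)
        scene.wall.U_s = kf.velocity(t)
        aortic.set_targets(kf, t)
        inflow.set_targets(kf, t)
        if step % params.weights_every == 0:
            for s in structures:
                s.update_weights_from_targets()

        # soft-start the outlet pressure so the quiescent initial field is
        # not slammed by the full Windkessel pressure (cycle 1 is discarded)
        ramp = 1.0 if params.startup_ramp <= 0 else float(
            np.clip(t / params.startup_ramp, 0.0, 1.0) ** 2
            * (3.0 - 2.0 * np.clip(t / params.startup_ramp, 0.0, 1.0))
        )
        diag = advance(
            state,
            structures,
            dt,
            bc=bc,
            psolver=psolver,
            outlet_pressure=mmhg_to_pa(p_out_mmhg) * ramp,
        )
        max_track = max(max_track, max(diag["tracking"].values()))

        q_ml_s = float(np.sum(state.u[-1, lo:hi])) * grid.h / ML
        p_out_mmhg = windkessel_update(wk, q_ml_s, dt)
        L_prev = scene.valve.L
        dp = aortic.update_state(state.p, grid, dt)
        inflow.update_state(state.p, grid, dt)
        L_now = scene.valve.L
        if L_prev <= 0.0 < L_now:
            valve_events.append((state.t, "open_start"))
        if L_prev < 1.0 <= L_now:
            valve_events.append((state.t, "open_end"))
        if L_prev >= 1.0 > L_now:
            valve_events.append((state.t, "close_start"))
        if L_prev > 0.0 >= L_now:
            valve_events.append((state.t, "close_end"))

        if step % params.sample_every == 0 or step == n_steps - 1:
            if mask is None or sample_count % params.mask_every == 0:
                poly = scene.boundary_vertices(scene.wall.D)
                fluid = interior_mask(poly, grid, decimate=params.mask_decimate)
                # integration domain ends at the outlet plane: the boundary
                # column carries the Dirichlet outlet condition, not interior
                # dissipation
                i_cut = int((scene.x_end - 3.0 * grid.h - grid.x0) / grid.h)
                fluid[i_cut:, :] = False
                valve_pts = np.vstack(
                    [s.chi for s in scene.valve.structures + scene.inflow_valve.structures]
                )
                band = structure_band_mask(valve_pts, grid, 1.5 * grid.h)
                mask = fluid & ~band
            sample_count += 1
            ploss = power_loss(state.u, state.v, mask, params.mu, grid)
            series.append(
                t + dt, dp, q_ml_s, ploss, scene.valve.L, cfl_number(state, dt), p_out_mmhg
            )
            if snapshot_callback is not None:
                snapshot_callback(state, scene, mask, sample_count)

    return ScenarioResult(
        label=placement.label if placement is not None else "baseline",
        metrics=series,
        scene=scene,
        state=state,
        dt=dt,
        kappa=kappa,
        eta=eta,
        max_tracking_error=max_track,
        # report the configured cycle, or the last complete one if the run
        # is shorter (the first cycle is only reported when it is the run)
        report_cycle=max(0, min(params.report_cycle, int(np.floor(params.n_cycles)) - 1)),
        valve_events=valve_events,
    )


def run_placements(
    config=None,
    placements: list | None = None,
    params: RunParams | None = None,
    progress=None,
) -> list:
    """Run a batch of placement scenarios, each on a fresh phantom.

    Failures are recorded (label -> exception) and remaining scenarios still
    run; returns (results, failures).
    """
    from .phantom import PhantomConfig, standard_placements

    cfg = config or PhantomConfig()
    placements = placements if placements is not None else standard_placements()
    params = params or RunParams()
    results, failures = [], {}
    for pl in placements:
        try:
            scene = make_phantom(cfg)
            if progress is not None:
                progress(pl.label)
            results.append(run_scenario(scene, params, placement=pl))
        except Exception as exc:  # noqa: BLE001 - batch isolation by contract
            failures[pl.label] = exc
    return results, failures
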