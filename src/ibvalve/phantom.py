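"""Synthetic contracting-chamber phantom with an implanted prosthetic valve.

The phantom is the 2D desk-scale stand-in for a CT-derived left heart: an
elliptical contracting chamber ("ventricle") joined to a straight outflow
channel ("aorta") that ends at the domain boundary (the Windkessel outlet),
plus a short inflow port on the far side of the chamber so the chamber can
refill in diastole. The inflow port carries a second instance of the same
reduced-order valve so that systolic ejection leaves through the outflow
channel only.

Wall motion is analytic and sampled at N keyframes over one cycle (20 by
default, the phase count of a gated CT reconstruction at every 5% of R-R):

* chamber boundary points move radially toward the chamber center with a
  blend weight that fades to zero at the channel and inflow junctions; the
  amplitude at each keyframe is solved exactly (the polygon area is quadratic
  in the amplitude) so the chamber area tracks A0 * (1 - EF * sin^2(pi t/T))
  and the configured ejection fraction is met to machine precision;
* outflow-channel walls translate axially (annular excursion) with a smooth
  ramp that vanishes at the junction and toward the outlet, which exercises
  the landing-zone/rigid-motion pipeline;
* the inflow stub is stationary.

Valve placements (baseline, ventricular translation, rotations about the
annulus center) are rigid maps of the whole valve; the wall is then locally
snapped onto the housing's outer profile ("apposition") so contact is
maintained with no through-gap, mirroring the annular contraction around the
housing that prevents artificial paravalvular leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import EulerianGrid
from .metrics import SampleClouds, disc_cloud
from .motion import MotionKeyframes, RigidTransform
from .solver import OutletSpec
from .structure import LagrangianStructure, resample_polyline
from .valve import ValveModel


def smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area (positive for counterclockwise order)."""
    v = np.asarray(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, motion and grid parameters of the synthetic phantom.

    Default dimensions approximate adult anatomy in-plane: a 6 x 4 cm
    chamber, a 2.3 cm outflow channel (23 mm valve analog) and a 2 cm valve
    annulus. The cycle period defaults to 1 s (heart rate is not an imaging
    output; it is a free parameter here).
    """

    chamber_semi_axis_x: float = 0.030  # m
    chamber_semi_axis_y: float = 0.020  # m
    channel_width: float = 0.023  # m
    channel_length: float | None = None  # m; None = to the domain edge
    period: float = 1.0  # s
    n_phases: int = 20
    ejection_fraction: float = 0.5
    annulus_diameter: float = 0.020  # m
    annulus_offset: float = 0.0135  # m downstream of the junction
    leaflet_count: int = 2
    apposition_margin: float = 0.0015  # m
    annular_excursion: float = 0.001  # m axial channel motion amplitude
    inflow_half_width: float = 0.007  # m
    inflow_annulus_diameter: float = 0.010  # m
    nx: int = 256
    ny: int = 128
    h: float = 5.0e-4  # m
    point_spacing: float | None = None  # m; None = h/2

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if not 0.0 < self.ejection_fraction < 1.0:
            raise ValueError("ejection fraction must lie strictly in (0, 1)")
        if self.channel_width < self.annulus_diameter:
            raise ValueError("channel width must be >= annulus diameter")
        for name in (
            "chamber_semi_axis_x",
            "chamber_semi_axis_y",
            "channel_width",
            "period",
            "annulus_diameter",
            "apposition_margin",
            "h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.leaflet_count != 2:
            raise ValueError("the 2D phantom supports exactly 2 leaflets")

    @property
    def spacing(self) -> float:
        return self.point_spacing if self.point_spacing is not None else 0.5 * self.h

    def grid(self) -> EulerianGrid:
        return EulerianGrid(self.nx, self.ny, self.h)


@dataclass(frozen=True)
class Placement:
    """Rigid valve placement: rotation (degrees) about the annulus center
    (a pivot on the annulus centerline), then translation [m]."""

    label: str
    translation: tuple = (0.0, 0.0)
    rotation_deg: float = 0.0

    def transform(self, pivot: np.ndarray) -> RigidTransform:
        ang = np.deg2rad(self.rotation_deg)
        R = RigidTransform(ang, np.zeros(2)).rotation_matrix
        trans = np.asarray(pivot) - R @ np.asarray(pivot) + np.asarray(self.translation)
        return RigidTransform(ang, trans)


def standard_placements(ventricular_translation: float = 0.006) -> list:
    """The four-candidate placement set: baseline, 6 mm ventricular
    translation, and 14 deg / 27 deg rotations about the annulus center."""
    return [
        Placement("baseline"),
        Placement("translated_6mm", translation=(-ventricular_translation, 0.0)),
        Placement("rotated_14deg", rotation_deg=14.0),
        Placement("rotated_27deg", rotation_deg=27.0),
    ]


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------
@dataclass
class PhantomScene:
    config: PhantomConfig
    grid: EulerianGrid
    wall: LagrangianStructure
    valve: ValveModel
    inflow_valve: ValveModel
    clouds: SampleClouds
    inflow_clouds: SampleClouds
    outlet: OutletSpec
    baffles: LagrangianStructure = None
    keyframes: MotionKeyframes = None
    # geometry bookkeeping
    centerline_y: float = 0.0
    chamber_center: np.ndarray = None
    x_junction: float = 0.0
    x_end: float = 0.0
    housing_half_length: float = 0.0
    # wall point classification (indices into wall.X)
    idx_arcs: list = field(default_factory=list)  # list of contiguous runs
    idx_channel: np.ndarray = None
    chamber_poly_idx: np.ndarray = None
    # analytic motion data
    radial_dir: np.ndarray = None  # (n, 2) blend-weighted direction to center
    axial_ramp: np.ndarray = None  # (n,)
    alphas: np.ndarray = None  # per-keyframe contraction amplitude

    # -- analytic motion -----------------------------------------------------
    def systolic_profile(self, t) -> np.ndarray:
        """g(t) in [0, 1]: contraction fraction over the cycle.

        Waveform approximating a ventricular volume curve with explicit
        valve-transition phases:

        * pre-ejection (first 8% of the cycle): a small (1% of EF), slow
          contraction that pressurizes the chamber and opens the outflow
          valve quasi-statically before any significant flow -- the analog
          of isovolumetric contraction plus early ejection;
        * main ejection: quintic-smoothstep contraction to g = 1 at 35% of
          the cycle;
        * pre-filling (8%): a small relaxation whose gentle suction closes
          the outflow valve at low reverse flow (isovolumetric relaxation);
        * main filling to 65% of the cycle, then diastasis (quiescent).

        The cycle starts inside diastasis (systole begins a quarter period
        in), so a simulation started from rest settles through a quiescent
        phase before the first contraction. All segments are quintic
        smoothsteps (zero first and second derivatives at the joints);
        g(0) = 0 and the waveform is periodic."""

        def s5(x):
            x = np.clip(x, 0.0, 1.0)
            return x**3 * (10.0 - 15.0 * x + 6.0 * x**2)

        T = self.config.period
        t_pre = 0.12 * T
        ts = 0.35 * T
        td = 0.30 * T
        g_pre_up = 0.10
        g_pre_dn = 0.10
        t = np.mod(np.asarray(t, dtype=float) - 0.25 * T, T)
        up = np.where(
            t < t_pre,
            g_pre_up * s5(t / t_pre),
            g_pre_up + (1.0 - g_pre_up) * s5((t - t_pre) / (ts - t_pre)),
        )
        down = np.where(
            t - ts < t_pre,
            1.0 - g_pre_dn * s5((t - ts) / t_pre),
            (1.0 - g_pre_dn) * (1.0 - s5((t - ts - t_pre) / (td - t_pre))),
        )
        return np.where(t < ts, up, down)

    def chamber_polygon(self, displacement: np.ndarray | None = None) -> np.ndarray:
        """Ordered chamber polygon vertices (closed implicitly), optionally
        displaced; the shoelace oracle for the ejection fraction."""
        pts = self.wall.X[self.chamber_poly_idx]
        if displacement is not None:
            pts = pts + displacement[self.chamber_poly_idx]
        return pts

    def boundary_vertices(self, displacement: np.ndarray | None = None) -> np.ndarray:
        """All wall points in polygon order; closing the loop adds the outlet
        and inflow-mouth segments."""
        pts = self.wall.X
        if displacement is not None:
            pts = pts + displacement
        return pts

    def _ramp(self, x: np.ndarray) -> np.ndarray:
        """Axial-excursion ramp along the channel: 0 at the junction, 1 over
        the valve region, 0 toward the outlet."""
        up = smoothstep((x - self.x_junction) / 0.0055)
        x_d0 = self.x_junction + 0.030
        x_d1 = min(self.x_end - 0.008, x_d0 + 0.022)
        down = 1.0 - smoothstep((x - x_d0) / max(x_d1 - x_d0, 1e-9))
        return np.where(x <= self.x_junction, 0.0, up * down)

    def _recompute_motion_data(self) -> None:
        n = self.wall.n_points
        self.axial_ramp = np.zeros(n)
        ch = self.idx_channel
        self.axial_ramp[ch] = self._ramp(self.wall.X[ch, 0])

    def _displacement_at_amplitude(self, alpha: float, g: float) -> np.ndarray:
        d = alpha * self.radial_dir.copy()
        d[:, 0] -= self.config.annular_excursion * g * self.axial_ramp
        return d

    def _solve_alpha(self, target_area: float, phase: int) -> float:
        idx = self.chamber_poly_idx
        p = self.wall.X[idx]
        u = self.radial_dir[idx]
        a0 = shoelace_area(p)
        ap = shoelace_area(p + u)
        am = shoelace_area(p - u)
        c1 = 0.5 * (ap - am)
        c2 = 0.5 * (ap + am) - a0
        roots = np.roots([c2, c1, a0 - target_area]) if c2 != 0 else np.array(
            [(target_area - a0) / c1]
        )
        roots = roots[np.abs(roots.imag) < 1e-12].real if roots.dtype.kind == "c" else roots
        roots = roots[roots >= -1e-12]
        if len(roots) == 0:
            raise ValueError(
                f"phase {phase}: configured ejection fraction unreachable by the "
                "chamber contraction (no admissible amplitude)"
            )
        return float(np.min(roots))

    def rebuild_keyframes(self) -> None:
        """(Re)build displacement keyframes from the analytic motion laws,
        solving the contraction amplitude at every phase so the chamber area
        follows A0 * (1 - EF * g(t)) exactly."""
        cfg = self.config
        self._recompute_motion_data()
        t_k = np.arange(cfg.n_phases) * cfg.period / cfg.n_phases
        g_k = self.systolic_profile(t_k)
        A0 = shoelace_area(self.chamber_polygon())
        D = np.zeros((self.wall.n_points, cfg.n_phases, 2))
        alphas = np.zeros(cfg.n_phases)
        # blend weight magnitude per point relative to its distance to center
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.linalg.norm(self.radial_dir, axis=1) / np.maximum(
                np.linalg.norm(self.chamber_center - self.wall.X, axis=1), 1e-30
            )
        for k in range(cfg.n_phases):
            target = A0 * (1.0 - cfg.ejection_fraction * g_k[k])
            alphas[k] = 0.0 if g_k[k] == 0.0 else self._solve_alpha(target, k)
            if np.max(alphas[k] * rel) >= 0.95:
                raise ValueError(
                    f"phase {k}: chamber contraction would self-intersect "
                    f"(amplitude {alphas[k]:.3f} collapses the boundary)"
                )
            D[:, k, :] = self._displacement_at_amplitude(alphas[k], g_k[k])
        self.alphas = alphas
        self.keyframes = MotionKeyframes(t_k, D, cfg.period)

    def measured_ejection_fraction(self) -> float:
        """(A_max - A_min)/A_max of the chamber polygon across keyframes."""
        areas = [
            shoelace_area(self.chamber_polygon(self.keyframes.displacements[:, k, :]))
            for k in range(self.config.n_phases)
        ]
        return (max(areas) - min(areas)) / max(areas)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------
def _ellipse_arc(center, a, b, phi0, phi1, spacing):
    """Points on an ellipse arc at roughly uniform spacing."""
    approx_len = abs(phi1 - phi0) * max(a, b)
    n = max(8, int(np.ceil(approx_len / spacing)) + 1)
    phi = np.linspace(phi0, phi1, n)
    return np.column_stack([center[0] + a * np.cos(phi), center[1] + b * np.sin(phi)])


def _line(p0, p1, spacing):
    return resample_polyline(np.array([p0, p1]), spacing)


def make_valve(config: PhantomConfig, *, inflow: bool = False) -> ValveModel:
    """Build a bileaflet valve: rigid housing constriction + two leaflets
    with matched closed/open point sets.

    The aortic valve sits in the outflow channel at the configured annulus
    offset; with `inflow=True` a smaller mirror-image valve for the inflow
    port is built instead (opens on reversed gradient by cloud convention).
    """
    if config.annulus_diameter > config.channel_width:
        raise ValueError("annulus diameter exceeds channel width")
    geo = _phantom_layout(config)
    cy = geo["cy"]
    sp = config.spacing
    if inflow:
        r_a = 0.5 * config.inflow_annulus_diameter
        w2 = config.inflow_half_width
        x_a = geo["x_stub_start"] + 0.001 + 0.002  # housing center in the stub
        hl = 0.002
    else:
        r_a = 0.5 * config.annulus_diameter
        w2 = 0.5 * config.channel_width
        x_a = geo["x_junction"] + config.annulus_offset
        hl = 0.6 * r_a

    loops, segs, pts = [], [], []
    for sgn in (+1.0, -1.0):
        quad = np.array(
            [
                [x_a - hl, cy + sgn * w2],
                [x_a - hl, cy + sgn * r_a],
                [x_a + hl, cy + sgn * r_a],
                [x_a + hl, cy + sgn * w2],
            ]
        )
        loop = resample_polyline(quad, sp, closed=True)
        start = sum(len(p) for p in pts)
        pts.append(loop)
        segs.append(np.append(np.arange(start, start + len(loop)), start))
    # when the housing is thinner than the kernel width its outer and inner
    # edges overlap (on top of the apposed wall line); half penalty keeps the
    # summed collective stiffness of the stacked lines inside the stability
    # margin at coarse resolutions
    housing_scale = 1.0 if (w2 - r_a) >= 3.0 * config.h - 1e-9 else 0.5
    housing = LagrangianStructure(
        X=np.vstack(pts),
        segments=segs,
        role="housing",
        penalty_scale=housing_scale,
        name="housing_in" if inflow else "housing",
    )

    n_lf = 40
    tip_half_gap = 0.2 * config.h
    leaflets, closed_cfgs, open_cfgs = [], [], []
    for sgn in (+1.0, -1.0):
        hinge = np.array([x_a - 0.4 * r_a if not inflow else x_a - 0.75 * hl, cy + sgn * r_a])
        tip_closed = np.array(
            [x_a + (0.2 * r_a if not inflow else 1.75 * hl), cy + sgn * tip_half_gap]
        )
        # aortic leaflets open into a conical nozzle (effective orifice
        # narrower than the annulus, as for a deployed bioprosthesis) so the
        # systolic jet carries a measurable transvalvular gradient; the
        # inflow leaflets open flat against their housing (low resistance)
        tip_open = np.array(
            [
                x_a + (0.52 * r_a if not inflow else 1.9 * hl),
                cy + sgn * (0.30 * r_a if not inflow else r_a - 1.2 * config.h),
            ]
        )
        s = np.linspace(0.0, 1.0, n_lf)[:, None]
        # double-layer leaflet: a second point row offset 0.75 h upstream
        # doubles the closed leaflet's through-flow resistance (the pressure
        # jump splits over two penalty bands in series); each row carries
        # half the penalty coefficients so the collective stiffness and the
        # explicit stability limit are unchanged
        off = np.array([-0.75 * config.h, 0.0])
        closed = np.vstack([hinge + s * (tip_closed - hinge), hinge + off + s * (tip_closed - hinge)])
        opened = np.vstack([hinge + s * (tip_open - hinge), hinge + off + s * (tip_open - hinge)])
        leaflets.append(
            LagrangianStructure(
                X=closed.copy(),
                segments=[np.arange(n_lf), np.arange(n_lf, 2 * n_lf)],
                role="leaflet",
                penalty_scale=0.5,
                name=("leaflet_in_" if inflow else "leaflet_") + ("top" if sgn > 0 else "bot"),
            )
        )
        closed_cfgs.append(closed)
        open_cfgs.append(opened)

    return ValveModel(
        housing=housing,
        leaflets=leaflets,
        leaflets_closed=closed_cfgs,
        leaflets_open=open_cfgs,
        annulus_center=np.array([x_a, cy]),
        annulus_axis=np.array([1.0, 0.0]),
        annulus_diameter=2 * r_a,
    )


def _phantom_layout(config: PhantomConfig) -> dict:
    g = config.grid()
    x0, x1, y0, y1 = g.extent
    cy = 0.5 * (y0 + y1)
    a, b = config.chamber_semi_axis_x, config.chamber_semi_axis_y
    cx = x0 + 0.010 + a
    wch2 = 0.5 * config.channel_width
    win = config.inflow_half_width
    if wch2 >= b or win >= b:
        raise ValueError("channel/inflow width must be smaller than the chamber height")
    dxj = a * np.sqrt(1.0 - (wch2 / b) ** 2)
    x_junction = cx + dxj
    # channel walls run onto the domain boundary (the solver's clamped
    # kernels handle structure points at the boundary) so the outlet corner
    # is sealed by wall + solid boundary with no aperture
    x_end_max = x1
    x_end = (
        min(x_junction + config.channel_length, x_end_max)
        if config.channel_length is not None
        else x_end_max
    )
    dxs = a * np.sqrt(1.0 - (win / b) ** 2)
    x_stub_j = cx - dxs
    x_stub_start = x0 + 8.0 * config.h
    if x_stub_start >= x_stub_j:
        raise ValueError("chamber leaves no room for the inflow stub")
    return dict(
        cy=cy,
        center=np.array([cx, cy]),
        a=a,
        b=b,
        wch2=wch2,
        win=win,
        x_junction=x_junction,
        x_end=x_end,
        x_stub_j=x_stub_j,
        x_stub_start=x_stub_start,
        phi_junction=np.arcsin(wch2 / b),
        phi_stub=np.pi - np.arcsin(win / b),
    )


def make_phantom(config: PhantomConfig | None = None) -> PhantomScene:
    """Build the full phantom scene: wall, valves, keyframes, sample clouds.

    Raises if the configured contraction would self-intersect at any phase.
    """
    cfg = config or PhantomConfig()
    geo = _phantom_layout(cfg)
    sp = cfg.spacing
    cy, c = geo["cy"], geo["center"]

    # --- wall pieces, polygon order (counterclockwise, two openings) -------
    pieces = []  # (points, kind)
    pieces.append((_line((geo["x_end"], cy + geo["wch2"]), (geo["x_junction"], cy + geo["wch2"]), sp), "channel"))
    pieces.append((_ellipse_arc(c, geo["a"], geo["b"], geo["phi_junction"], geo["phi_stub"], 0.5 * sp), "arc"))
    pieces.append((_line((geo["x_stub_j"], cy + geo["win"]), (geo["x_stub_start"], cy + geo["win"]), sp), "stub"))
    mouth_break = None  # polyline break between pieces 2 and 3
    pieces.append((_line((geo["x_stub_start"], cy - geo["win"]), (geo["x_stub_j"], cy - geo["win"]), sp), "stub"))
    pieces.append((_ellipse_arc(c, geo["a"], geo["b"], -geo["phi_stub"], -geo["phi_junction"], 0.5 * sp), "arc"))
    pieces.append((_line((geo["x_junction"], cy - geo["wch2"]), (geo["x_end"], cy - geo["wch2"]), sp), "channel"))

    pts_list, kinds, seg_breaks = [], [], []
    count = 0
    for i, (p, kind) in enumerate(pieces):
        if i in (1, 2, 4, 5):  # drop duplicated junction point
            p = p[1:]
        pts_list.append(p)
        kinds.extend([kind] * len(p))
        count += len(p)
        if i == 2:
            seg_breaks.append(count)  # inflow mouth: split polyline here
    X = np.vstack(pts_list)
    kinds = np.array(kinds)
    br = seg_breaks[0]
    segments = [np.arange(0, br), np.arange(br, len(X))]
    wall = LagrangianStructure(X=X, segments=segments, role="wall", name="wall")

    idx_channel = np.flatnonzero(kinds == "channel")
    idx_arc = np.flatnonzero(kinds == "arc")
    # contiguous arc runs (upper, lower)
    splits = np.where(np.diff(idx_arc) > 1)[0] + 1
    arc_runs = np.split(idx_arc, splits)

    # radial blend direction with arc-length fade at the arc ends
    radial_dir = np.zeros_like(X)
    L_blend = 0.013
    for run in arc_runs:
        p = X[run]
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(p, axis=0), axis=1))])
        w = smoothstep(np.minimum(s, s[-1] - s) / L_blend)
        radial_dir[run] = w[:, None] * (c - p)

    chamber_poly_idx = np.flatnonzero(X[:, 0] <= geo["x_junction"] + 1e-12)

    grid = cfg.grid()
    # outlet band: boundary cells spanning the channel opening, inset two
    # cells from the wall lines so no open boundary face sits inside the
    # walls' kernel layer (the outlet behaves like a port flange)
    j_lo = int(np.ceil((cy - geo["wch2"] - grid.y0) / grid.h)) + 2
    j_hi = int(np.floor((cy + geo["wch2"] - grid.y0) / grid.h)) - 2
    outlet = OutletSpec("right", j_lo, j_hi)

    valve = make_valve(cfg)
    inflow_valve = make_valve(cfg, inflow=True)
    # the inflow port is a phantom fixture, not the device under study: it
    # must shut promptly when the chamber pressurizes (or the pre-ejection
    # volume bleeds out of the port and the chamber never loads the outflow
    # valve) and open promptly and repeatably on diastolic suction (or the
    # refill jet varies cycle to cycle); low thresholds and a faster rate
    # avoid the dead-band hover on both transitions
    inflow_valve.P_close_mmhg = 0.3
    inflow_valve.P_open_mmhg = 0.3
    inflow_valve.R_leaf = 40.0
    d_ann = cfg.annulus_diameter
    x_a = valve.annulus_center[0]
    clouds = SampleClouds(
        lv=disc_cloud((x_a - d_ann, cy), 0.004),
        aorta=disc_cloud((x_a + d_ann, cy), 0.004),
    )
    inflow_clouds = SampleClouds(
        lv=disc_cloud((geo["x_stub_start"] - 0.002, cy), 0.001),  # outside (drives opening)
        aorta=disc_cloud((geo["x_stub_j"] + 0.006, cy), 0.003),  # chamber side
    )

    scene = PhantomScene(
        config=cfg,
        grid=grid,
        wall=wall,
        valve=valve,
        inflow_valve=inflow_valve,
        clouds=clouds,
        inflow_clouds=inflow_clouds,
        outlet=outlet,
        centerline_y=cy,
        chamber_center=c,
        x_junction=geo["x_junction"],
        x_end=geo["x_end"],
        housing_half_length=0.6 * 0.5 * cfg.annulus_diameter,
        idx_arcs=arc_runs,
        idx_channel=idx_channel,
        chamber_poly_idx=chamber_poly_idx,
        radial_dir=radial_dir,
    )
    scene.rebuild_keyframes()
    return scene


# ---------------------------------------------------------------------------
# implantation
# ---------------------------------------------------------------------------
def implant_valve(valve: ValveModel, scene: PhantomScene, placement: Placement) -> ValveModel:
    """Place the valve rigidly and snap the wall onto the housing (apposition).

    Rotation is about the annulus center (a pivot on the centerline), then
    translation. Channel-wall points within the housing's axial span are
    placed exactly on the housing outer profile; a smoothstep transition band
    blends back to the undisturbed wall so no through-gap larger than the
    apposition margin exists. The wall's reference geometry changes, so the
    motion keyframes are rebuilt consistently for all phases.
    """
    cfg = scene.config
    tr = placement.transform(valve.annulus_center)
    new_valve = valve.transformed(tr)
    new_valve.L = valve.L

    hl = scene.housing_half_length
    wch2 = 0.5 * cfg.channel_width
    ac = new_valve.annulus_center
    axis = new_valve.annulus_axis
    nrm = np.array([-axis[1], axis[0]])

    hx = new_valve.housing.X
    if np.any(hx[:, 0] < scene.x_junction - 1e-12) or np.any(
        hx[:, 0] > scene.x_end - 2 * cfg.h
    ):
        raise ValueError(
            f"placement {placement.label!r}: housing exits the channel axially"
        )
    protrusion = np.max(np.abs(hx[:, 1] - scene.centerline_y)) - wch2
    if protrusion > 0.5 * new_valve.annulus_diameter / 2.0 + cfg.apposition_margin:
        raise ValueError(
            f"placement {placement.label!r}: housing exits the channel "
            f"(protrusion {protrusion:.4g} m beyond the wall)"
        )
    side_before = np.sign(valve.housing.X[:, 1] - scene.centerline_y)
    side_after = np.sign(hx[:, 1] - scene.centerline_y)
    if np.any(side_before * side_after < 0):
        raise ValueError(
            f"placement {placement.label!r}: housing crosses the channel "
            "centerline and would intersect the far wall"
        )

    # apposition: snap channel-wall points vertically onto the housing's
    # outer envelope (contact profile), with a smooth taper back to the
    # undisturbed wall beyond the housing ends. Identity and pure axial
    # translations leave the wall bit-identical; rotations make the wall
    # wrap both the protruding and the recessed housing corners so contact
    # is maintained with no through-gap.
    wall = scene.wall
    Xw = wall.X.copy()
    ch = scene.idx_channel
    cy = scene.centerline_y
    L_t = 0.004  # taper length beyond the housing ends
    r_a = new_valve.annulus_diameter / 2.0
    for sgn in (+1.0, -1.0):
        profile = np.array(
            [
                [-hl, sgn * r_a],
                [-hl, sgn * wch2],
                [hl, sgn * wch2],
                [hl, sgn * r_a],
            ]
        )
        # valve frame -> world
        prof = ac + profile[:, :1] * axis + profile[:, 1:] * nrm
        samp = resample_polyline(prof, 0.25 * cfg.h)
        xs, ys = samp[:, 0], samp[:, 1]
        dx = 0.5 * cfg.h
        xg = np.arange(xs.min(), xs.max() + dx, dx)
        bins = np.clip(np.round((xs - xs.min()) / dx).astype(int), 0, len(xg) - 1)
        env = np.full(len(xg), -np.inf if sgn > 0 else np.inf)
        (np.maximum if sgn > 0 else np.minimum).at(env, bins, ys)
        filled = np.isfinite(env)
        xg, env = xg[filled], env[filled]

        side_pts = ch[np.sign(Xw[ch, 1] - cy) == sgn]
        x = Xw[side_pts, 0]
        inside = (x >= xg[0]) & (x <= xg[-1])
        y_env = np.interp(x, xg, env)
        # taper: 0 on the envelope, 1 at the undisturbed wall
        s = np.where(
            inside,
            0.0,
            smoothstep(np.minimum(np.abs(x - xg[0]), np.abs(x - xg[-1])) / L_t),
        )
        y_new = (1.0 - s) * np.where(inside, y_env, np.interp(
            np.clip(x, xg[0], xg[-1]), xg, env)) + s * Xw[side_pts, 1]
        Xw[side_pts, 1] = y_new
    wall.X = Xw
    wall.chi = Xw.copy()
    wall.D = np.zeros_like(Xw)
    wall.U_s = np.zeros_like(Xw)

    scene.valve = new_valve
    scene.rebuild_keyframes()
    return new_valve
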