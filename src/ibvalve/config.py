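"""TOML run configuration: phantom geometry, fluid/solver/penalty settings,
Windkessel parameters and the placement scenario batch.

All physical quantities carry explicit unit suffixes in key names. A minimal
configuration is an empty file: every key has the package default. Example:

    [phantom]
    ejection_fraction = 0.5
    period_s = 1.0

    [fluid]
    rho_kg_m3 = 1060.0
    mu_pa_s = 0.2

    [solver]
    cfl_target = 0.2
    n_cycles = 3

    [wk]
    r1_mmhg_s_per_ml = 0.000408
    r2_mmhg_s_per_ml = 0.00793
    c_ml_per_mmhg = 155.4
    p0_mmhg = 6.6

    [valve]
    r_leaf = 20.0
    p_open_mmhg = 1.0
    p_close_mmhg = 1.0

    [[scenarios]]
    label = "baseline"

    [[scenarios]]
    label = "rotated_27deg"
    rotation_deg = 27.0
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .phantom import Placement, PhantomConfig, standard_placements
from .simulation import RunParams

_PHANTOM_KEYS = {
    "chamber_semi_axis_x_m": "chamber_semi_axis_x",
    "chamber_semi_axis_y_m": "chamber_semi_axis_y",
    "channel_width_m": "channel_width",
    "channel_length_m": "channel_length",
    "period_s": "period",
    "n_phases": "n_phases",
    "ejection_fraction": "ejection_fraction",
    "annulus_diameter_m": "annulus_diameter",
    "annulus_offset_m": "annulus_offset",
    "leaflet_count": "leaflet_count",
    "apposition_margin_m": "apposition_margin",
    "annular_excursion_m": "annular_excursion",
    "nx": "nx",
    "ny": "ny",
    "h_m": "h",
}

_RUN_KEYS = {
    ("fluid", "rho_kg_m3"): "rho",
    ("fluid", "mu_pa_s"): "mu",
    ("solver", "cfl_target"): "cfl_target",
    ("solver", "dt_fixed_s"): "dt_fixed",
    ("solver", "n_cycles"): "n_cycles",
    ("solver", "sample_every"): "sample_every",
    ("solver", "seed"): "seed",
    ("penalty", "kappa"): "kappa",
    ("penalty", "eta"): "eta",
    ("penalty", "safety"): "penalty_safety",
    ("wk", "r1_mmhg_s_per_ml"): "wk_r1",
    ("wk", "r2_mmhg_s_per_ml"): "wk_r2",
    ("wk", "c_ml_per_mmhg"): "wk_c",
    ("wk", "p0_mmhg"): "wk_p0",
}


@dataclass
class RunConfig:
    phantom: PhantomConfig
    params: RunParams
    placements: list
    valve: dict = field(default_factory=dict)  # r_leaf, p_open_mmhg, p_close_mmhg
    raw_text: str = ""

    def apply_valve_settings(self, valve) -> None:
        if "r_leaf" in self.valve:
            valve.R_leaf = float(self.valve["r_leaf"])
        if "p_open_mmhg" in self.valve:
            valve.P_open_mmhg = float(self.valve["p_open_mmhg"])
        if "p_close_mmhg" in self.valve:
            valve.P_close_mmhg = float(self.valve["p_close_mmhg"])


def load_config(path) -> RunConfig:
    """Parse a TOML run configuration; missing keys take package defaults."""
    raw = Path(path).read_text()
    doc = tomllib.loads(raw)
    ph_kwargs = {}
    for key, attr in _PHANTOM_KEYS.items():
        if key in doc.get("phantom", {}):
            ph_kwargs[attr] = doc["phantom"][key]
    run_kwargs = {}
    for (sec, key), attr in _RUN_KEYS.items():
        if key in doc.get(sec, {}):
            run_kwargs[attr] = doc[sec][key]
    placements = []
    for sc in doc.get("scenarios", []):
        placements.append(
            Placement(
                label=sc.get("label", f"scenario_{len(placements)}"),
                translation=tuple(sc.get("translation_m", (0.0, 0.0))),
                rotation_deg=float(sc.get("rotation_deg", 0.0)),
            )
        )
    if not placements:
        placements = standard_placements()
    labels = [p.label for p in placements]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")
    return RunConfig(
        phantom=PhantomConfig(**ph_kwargs),
        params=RunParams(**run_kwargs),
        placements=placements,
        valve=doc.get("valve", {}),
        raw_text=raw,
    )
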