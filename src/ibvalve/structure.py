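"""Lagrangian structures: point sets with polyline connectivity.

A structure is a set of material points X (reference positions) with current
positions chi, organised into one or more open or closed polyline segments.
Each point carries an arc-length quadrature weight so that sums over points
approximate line integrals over the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLES = ("wall", "housing", "leaflet")


def _segment_weights(points: np.ndarray, segments: list[np.ndarray]) -> np.ndarray:
    """Arc-length weight per point: half the length of the adjacent edges."""
    w = np.zeros(len(points))
    for seg in segments:
        pts = points[seg]
        edge = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        w_seg = np.zeros(len(seg))
        w_seg[:-1] += 0.5 * edge
        w_seg[1:] += 0.5 * edge
        np.add.at(w, seg, w_seg)
    return w


@dataclass
class LagrangianStructure:
    """Point set with polyline connectivity and penalty-coupling state.

    Parameters
    ----------
    X : (n, 2) reference positions [m]
    segments : list of index arrays; each array is a polyline (a closed loop
        repeats its first index at the end)
    role : one of 'wall', 'housing', 'leaflet'
    kappa, eta : penalty spring stiffness [Pa/m] and damping [Pa*s/m] per
        unit arc length (2D traction per metre of mistracking)
    """

    X: np.ndarray
    segments: list[np.ndarray]
    role: str = "wall"
    kappa: float = 0.0
    eta: float = 0.0
    penalty_scale: float = 1.0  # per-structure factor on auto kappa/eta
    name: str = ""
    chi: np.ndarray = field(default=None)  # current positions
    weights: np.ndarray = field(default=None)
    D: np.ndarray = field(default=None)  # target displacement
    U_s: np.ndarray = field(default=None)  # target velocity
    pinned: np.ndarray = field(default=None)  # bool mask: chi held on target

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 2:
            raise ValueError("X must be (n, 2)")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        self.segments = [np.asarray(s, dtype=int) for s in self.segments]
        if self.chi is None:
            self.chi = self.X.copy()
        if self.weights is None:
            self.weights = _segment_weights(self.X, self.segments)
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")
        if self.D is None:
            self.D = np.zeros_like(self.X)
        if self.U_s is None:
            self.U_s = np.zeros_like(self.X)

    @property
    def n_points(self) -> int:
        return len(self.X)

    def target_positions(self) -> np.ndarray:
        return self.X + self.D

    def tracking_error(self) -> float:
        """Max distance between current and target positions [m]."""
        return float(np.max(np.linalg.norm(self.chi - self.target_positions(), axis=1)))

    def update_weights_from_targets(self) -> None:
        """Recompute arc-length quadrature weights on the target (deformed)
        configuration. Keeps the collective penalty stiffness per unit length
        constant when the structure compresses or stretches."""
        self.weights = _segment_weights(self.X + self.D, self.segments)

    def copy(self) -> "LagrangianStructure":
        return LagrangianStructure(
            X=self.X.copy(),
            segments=[s.copy() for s in self.segments],
            role=self.role,
            kappa=self.kappa,
            eta=self.eta,
            penalty_scale=self.penalty_scale,
            name=self.name,
            chi=self.chi.copy(),
            weights=self.weights.copy(),
            D=self.D.copy(),
            U_s=self.U_s.copy(),
            pinned=None if self.pinned is None else self.pinned.copy(),
        )


def polyline(points: np.ndarray, closed: bool = False, **kw) -> LagrangianStructure:
    """Build a structure from an ordered (n, 2) point array."""
    points = np.asarray(points, dtype=float)
    idx = np.arange(len(points))
    if closed:
        idx = np.append(idx, 0)
    return LagrangianStructure(X=points, segments=[idx], **kw)


def resample_polyline(vertices: np.ndarray, spacing: float, closed: bool = False) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length spacing.

    The returned points include the original endpoints (open) or wrap
    (closed, first point not repeated).
    """
    verts = np.asarray(vertices, dtype=float)
    if closed:
        verts = np.vstack([verts, verts[:1]])
    seglen = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    n = max(2, int(np.ceil(total / spacing)) + 1)
    si = np.linspace(0.0, total, n)
    x = np.interp(si, s, verts[:, 0])
    y = np.interp(si, s, verts[:, 1])
    pts = np.column_stack([x, y])
    if closed:
        pts = pts[:-1]
    return pts
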