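"""Keyframe wall motion and rigid-body valve motion.

Wall motion arrives as displacement keyframes at N phases over one cardiac
cycle (20 phases by default, matching gated CT reconstructions at every 5% of
the R-R interval). A shape-preserving piecewise cubic Hermite interpolant
(PCHIP) built on the periodic extension turns the keyframes into smooth,
C1, overshoot-free displacement and velocity histories.

The prosthetic valve is rigid: its motion is the least-squares rigid
transform (Horn's method) mapping the reference landing zone -- the annular
wall region in contact with the housing -- onto its displaced position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .structure import LagrangianStructure


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map x -> R(angle) x + translation (2D: angle about z)."""

    angle: float  # radians
    translation: np.ndarray  # (2,)

    @property
    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation_matrix.T + self.translation

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix
        return RigidTransform(-self.angle, -(R.T @ self.translation))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, np.zeros(2))


def fit_rigid_transform(ref_points: np.ndarray, cur_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid alignment of matched 2D point sets (Horn's method).

    The planar specialization of the quaternion cross-covariance construction:
    with both clouds centered, the optimal rotation angle is
    atan2(sum(ref x cur), sum(ref . cur)), which is always a proper rotation
    (no reflection or scaling), and the centroids map exactly.
    """
    ref = np.asarray(ref_points, dtype=float)
    cur = np.asarray(cur_points, dtype=float)
    if ref.shape != cur.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("ref and cur must be matched (n, 2) arrays")
    if len(ref) < 2:
        raise ValueError("need at least 2 points")
    rc = ref.mean(axis=0)
    cc = cur.mean(axis=0)
    r = ref - rc
    c = cur - cc
    if np.allclose(r, 0.0) and np.allclose(c, 0.0):
        if len(ref) > 1 and np.allclose(ref, ref[0]) and not np.allclose(cur, cur[0]):
            raise ValueError("degenerate reference configuration (coincident points)")
        # pure translation of a (nearly) degenerate cloud
        return RigidTransform(0.0, cc - rc)
    dot = float(np.sum(r * c))
    cross = float(np.sum(r[:, 0] * c[:, 1] - r[:, 1] * c[:, 0]))
    if dot == 0.0 and cross == 0.0:
        raise ValueError("degenerate configuration: rotation undetermined")
    angle = np.arctan2(cross, dot)
    Rm = RigidTransform(angle, np.zeros(2)).rotation_matrix
    return RigidTransform(angle, cc - Rm @ rc)


def fit_rigid_transform_3d(ref_points: np.ndarray, cur_points: np.ndarray):
    """Horn's quaternion absolute-orientation fit for 3D point sets.

    Returns (R, t) with R a proper 3x3 rotation. Builds the 4x4 symmetric
    matrix from the cross-covariance of the centered clouds; the unit
    eigenvector of the largest eigenvalue is the optimal quaternion, which is
    always a proper rotation (reflections cannot occur).
    """
    ref = np.asarray(ref_points, dtype=float)
    cur = np.asarray(cur_points, dtype=float)
    if ref.shape != cur.shape or ref.shape[1] != 3:
        raise ValueError("ref and cur must be matched (n, 3) arrays")
    rc, cc = ref.mean(axis=0), cur.mean(axis=0)
    M = (ref - rc).T @ (cur - cc)  # cross-covariance
    tr = np.trace(M)
    delta = np.array([M[1, 2] - M[2, 1], M[2, 0] - M[0, 2], M[0, 1] - M[1, 0]])
    N = np.empty((4, 4))
    N[0, 0] = tr
    N[0, 1:] = N[1:, 0] = delta
    N[1:, 1:] = M + M.T - tr * np.eye(3)
    evals, evecs = np.linalg.eigh(N)
    q = evecs[:, -1]  # max eigenvalue
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return R, cc - R @ rc


# ---------------------------------------------------------------------------
# keyframe interpolation
# ---------------------------------------------------------------------------
class MotionKeyframes:
    """Per-point displacement keyframes over one periodic cycle.

    Parameters
    ----------
    phase_times : (N,) strictly increasing, first entry 0, all < period
    displacements : (n_points, N, 2) displacement vectors [m]
    period : cycle period T [s]

    The interpolant is built on three concatenated cycles and evaluated on
    the middle one, so endpoint slopes come from the periodic extension
    rather than an invented boundary condition.
    """

    def __init__(self, phase_times: np.ndarray, displacements: np.ndarray, period: float):
        t = np.asarray(phase_times, dtype=float)
        D = np.asarray(displacements, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("phase times must be strictly increasing")
        if t[0] != 0.0:
            raise ValueError("first phase time must be 0")
        if period <= t[-1]:
            raise ValueError("period must exceed the last phase time")
        if D.ndim != 3 or D.shape[1] != len(t) or D.shape[2] != 2:
            raise ValueError("displacements must be (n_points, n_phases, 2)")
        self.phase_times = t
        self.displacements = D
        self.period = float(period)
        t_ext = np.concatenate([t - period, t, t + period, [2 * period]])
        D_ext = np.concatenate([D, D, D, D[:, :1]], axis=1)  # periodic wrap
        # PCHIP over time with points*components trailing
        self._interp = PchipInterpolator(t_ext, np.moveaxis(D_ext, 1, 0), axis=0)
        self._dinterp = self._interp.derivative()

    @property
    def n_points(self) -> int:
        return self.displacements.shape[0]

    def _wrap(self, t: float) -> float:
        if not np.isfinite(t):
            raise ValueError("time must be finite")
        return float(np.mod(t, self.period))

    def displacement(self, t: float) -> np.ndarray:
        """Target displacement D(t), shape (n_points, 2); exact at keyframes."""
        return np.asarray(self._interp(self._wrap(t)))

    def velocity(self, t: float) -> np.ndarray:
        """Target velocity U_s(t) = dD/dt, shape (n_points, 2)."""
        return np.asarray(self._dinterp(self._wrap(t)))

    def subset(self, indices: np.ndarray) -> "MotionKeyframes":
        return MotionKeyframes(
            self.phase_times, self.displacements[np.asarray(indices)], self.period
        )


def interp_displacement(kf: MotionKeyframes, t: float) -> np.ndarray:
    return kf.displacement(t)


def target_velocity(kf: MotionKeyframes, t: float) -> np.ndarray:
    return kf.velocity(t)


# ---------------------------------------------------------------------------
# landing zone
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class LandingZone:
    """Wall-point index set in contact with the valve housing at reference."""

    indices: np.ndarray
    ref_positions: np.ndarray


def point_polyline_distance(points: np.ndarray, structure: LagrangianStructure) -> np.ndarray:
    """Min distance from each point to the structure's polyline segments."""
    pts = np.asarray(points, dtype=float)
    dmin = np.full(len(pts), np.inf)
    for seg in structure.segments:
        a = structure.chi[seg[:-1]]  # (m, 2) edge starts
        b = structure.chi[seg[1:]]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0
        ap = pts[:, None, :] - a[None, :, :]  # (n, m, 2)
        s = np.clip(np.einsum("nmj,mj->nm", ap, ab) / denom, 0.0, 1.0)
        proj = a[None] + s[..., None] * ab[None]
        d = np.linalg.norm(pts[:, None, :] - proj, axis=2)
        dmin = np.minimum(dmin, d.min(axis=1))
    return dmin


def extract_landing_zone(
    wall: LagrangianStructure, housing: LagrangianStructure, threshold: float
) -> LandingZone:
    """Wall points within `threshold` of the housing polyline (nearest-neighbor)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = point_polyline_distance(wall.X, housing)
    idx = np.flatnonzero(d <= threshold)
    if len(idx) == 0:
        raise ValueError(
            f"no wall points within {threshold:g} m of the housing "
            f"(closest standoff {d.min():g} m): valve not in contact"
        )
    return LandingZone(indices=idx, ref_positions=wall.X[idx].copy())


def valve_rigid_motion(kf: MotionKeyframes, lz: LandingZone, t: float) -> RigidTransform:
    """Rigid transform carrying the reference landing zone to its position at t.

    The least-squares fit over all landing-zone points reproduces the mean
    translation exactly for translation-dominated motion.
    """
    D = kf.displacement(t)[lz.indices]
    return fit_rigid_transform(lz.ref_positions, lz.ref_positions + D)
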