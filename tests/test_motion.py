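"""Keyframe interpolation, landing-zone extraction and rigid registration."""

import numpy as np
import pytest

from ibvalve.motion import (
    LandingZone,
    MotionKeyframes,
    RigidTransform,
    extract_landing_zone,
    fit_rigid_transform,
    fit_rigid_transform_3d,
    valve_rigid_motion,
)
from ibvalve.structure import polyline


# ---------------------------------------------------------------------------
# PCHIP keyframes
# ---------------------------------------------------------------------------
def _make_kf(values, period=1.0):
    """One point, one displacement component from a list of phase values."""
    n = len(values)
    t = np.arange(n) * period / n
    D = np.zeros((1, n, 2))
    D[0, :, 0] = values
    return MotionKeyframes(t, D, period)


def test_interpolation_exact_at_keyframes():
    vals = [0.0, 0.3, -0.2, 0.7, 0.1]
    kf = _make_kf(vals)
    for k, v in enumerate(vals):
        assert kf.displacement(k / 5)[0, 0] == pytest.approx(v, abs=1e-14)


def test_constant_keyframes_give_constant_displacement_and_zero_velocity():
    kf = _make_kf([0.4] * 6)
    for t in np.linspace(0, 2.3, 17):
        assert kf.displacement(t)[0, 0] == pytest.approx(0.4, abs=1e-14)
        assert kf.velocity(t)[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_monotone_data_has_no_overshoot():
    """Dense-sampling oracle: the shape-preserving interpolant stays within
    the data range on each monotone run."""
    vals = [0.0, 0.1, 0.35, 0.6, 0.8, 0.9, 0.5, 0.2, 0.05, 0.01]
    kf = _make_kf(vals)
    t = np.linspace(0, 1, 10_000, endpoint=False)
    d = np.array([kf.displacement(ti)[0, 0] for ti in t])
    assert d.min() >= min(vals) - 1e-12
    assert d.max() <= max(vals) + 1e-12


def test_velocity_matches_finite_difference_of_displacement():
    vals = [0.0, 0.25, 0.6, 0.3, -0.1, -0.3]
    kf = _make_kf(vals)
    eps = 1e-6
    for t in (0.07, 0.33, 0.59, 0.92):
        fd = (kf.displacement(t + eps) - kf.displacement(t - eps)) / (2 * eps)
        assert kf.velocity(t)[0, 0] == pytest.approx(fd[0, 0], abs=1e-6)


def test_periodic_closure_and_c1_continuity():
    vals = [0.0, 0.5, 0.2, -0.4, 0.1, 0.3, -0.2]
    kf = _make_kf(vals)
    assert kf.velocity(0.0)[0, 0] == pytest.approx(kf.velocity(1.0)[0, 0], abs=1e-12)
    assert kf.displacement(1.37)[0, 0] == pytest.approx(
        kf.displacement(0.37)[0, 0], abs=1e-12
    )
    # left/right derivative agreement at interior knots (C1 continuity)
    eps = 1e-12
    for tk in kf.phase_times[1:]:
        left = kf.velocity(tk - eps)[0, 0]
        right = kf.velocity(tk + eps)[0, 0]
        assert abs(left - right) <= 1e-9


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        _make_kf([1.0, 2.0]).displacement(np.inf)
    with pytest.raises(ValueError, match="first phase"):
        MotionKeyframes(np.array([0.1, 0.5]), np.zeros((1, 2, 2)), 1.0)
    with pytest.raises(ValueError, match="increasing"):
        MotionKeyframes(np.array([0.0, 0.5, 0.4]), np.zeros((1, 3, 2)), 1.0)


# ---------------------------------------------------------------------------
# Horn rigid fit (2D planar specialization)
# ---------------------------------------------------------------------------
def test_identity_fit():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])
    tr = fit_rigid_transform(pts, pts)
    assert tr.angle == pytest.approx(0.0, abs=1e-15)
    assert np.allclose(tr.translation, 0.0, atol=1e-15)


def test_recovers_27_degree_rotation_plus_translation():
    rng = np.random.default_rng(7)
    ref = rng.standard_normal((12, 2)) * 0.01
    truth = RigidTransform(np.deg2rad(27.0), np.array([0.006, 0.0]))
    tr = fit_rigid_transform(ref, truth.apply(ref))
    assert tr.angle == pytest.approx(np.deg2rad(27.0), abs=1e-12)
    assert np.allclose(tr.translation, truth.translation, atol=1e-10)


def test_exact_recovery_over_many_random_rigid_motions(rng):
    for _ in range(1000):
        n = rng.integers(2, 30)
        ref = rng.standard_normal((n, 2))
        truth = RigidTransform(rng.uniform(-np.pi, np.pi), rng.standard_normal(2))
        tr = fit_rigid_transform(ref, truth.apply(ref))
        err = np.max(np.linalg.norm(tr.apply(ref) - truth.apply(ref), axis=1))
        assert err <= 1e-10


def test_least_squares_optimality_vs_rotation_grid(rng):
    """On noisy 5-point clouds the fit's residual is no worse than any
    rotation from a 3600-step brute-force grid with its optimal translation."""
    for _ in range(5):
        ref = rng.standard_normal((5, 2)) * 0.01
        truth = RigidTransform(rng.uniform(-np.pi, np.pi), rng.standard_normal(2) * 0.01)
        cur = truth.apply(ref) + 1e-4 * rng.standard_normal((5, 2))
        tr = fit_rigid_transform(ref, cur)
        rss_fit = np.sum((tr.apply(ref) - cur) ** 2)
        angles = np.linspace(-np.pi, np.pi, 3600, endpoint=False)
        best = np.inf
        rc, cc = ref.mean(axis=0), cur.mean(axis=0)
        for ang in angles:
            R = RigidTransform(ang, np.zeros(2)).rotation_matrix
            t = cc - R @ rc  # optimal translation for this rotation
            rss = np.sum((ref @ R.T + t - cur) ** 2)
            best = min(best, rss)
        assert rss_fit <= best + 1e-18


def test_degenerate_cloud_rejected():
    ref = np.zeros((4, 2))
    cur = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ValueError, match="degenerate"):
        fit_rigid_transform(ref, cur)
    with pytest.raises(ValueError):
        fit_rigid_transform(ref[:1], cur[:1])


def test_quaternion_path_recovers_3d_rotation(rng):
    from scipy.spatial.transform import Rotation

    ref = rng.standard_normal((10, 3))
    R_true = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
    t_true = np.array([0.1, -0.2, 0.05])
    R, t = fit_rigid_transform_3d(ref, ref @ R_true.T + t_true)
    assert np.allclose(R, R_true, atol=1e-10)
    assert np.allclose(t, t_true, atol=1e-10)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


def test_rigid_transform_inverse_roundtrip(rng):
    tr = RigidTransform(0.7, np.array([0.01, -0.02]))
    pts = rng.standard_normal((20, 2))
    back = tr.inverse().apply(tr.apply(pts))
    assert np.max(np.linalg.norm(back - pts, axis=1)) <= 1e-12


# ---------------------------------------------------------------------------
# landing zone
# ---------------------------------------------------------------------------
def _wall_and_housing():
    wall = polyline(np.column_stack([np.linspace(0, 1, 101), np.zeros(101)]))
    housing = polyline(np.array([[0.40, 0.0005], [0.45, 0.0005]]))
    return wall, housing


def test_landing_zone_threshold_behaviors():
    wall, housing = _wall_and_housing()
    lz_all = extract_landing_zone(wall, housing, threshold=10.0)
    assert len(lz_all.indices) == wall.n_points
    with pytest.raises(ValueError, match="not in contact"):
        extract_landing_zone(wall, housing, threshold=1e-5)
    with pytest.raises(ValueError):
        extract_landing_zone(wall, housing, threshold=-1.0)


def test_landing_zone_matches_brute_force_count():
    wall, housing = _wall_and_housing()
    # wall spacing 0.01; points with x in [0.40-d, 0.45+d] where the offset
    # 0.0005 keeps the distance within 1 mm
    lz = extract_landing_zone(wall, housing, threshold=1e-3)
    d = np.full(wall.n_points, np.inf)
    for q, p in enumerate(wall.X):
        d[q] = min(
            np.linalg.norm(p - np.array([0.40, 0.0005])),
            np.linalg.norm(p - np.array([0.45, 0.0005])),
            abs(p[1] - 0.0005) if 0.40 <= p[0] <= 0.45 else np.inf,
        )
    expected = np.flatnonzero(d <= 1e-3)
    assert np.array_equal(lz.indices, expected)


def test_valve_rigid_motion_identity_translation_and_rigidity():
    wall, _ = _wall_and_housing()
    n = wall.n_points
    t_ph = np.arange(4) * 0.25
    D = np.zeros((n, 4, 2))
    D[:, 1, :] = [0.003, -0.001]  # pure translation at phase 1
    D[:, 2, :] = [0.006, -0.002]
    D[:, 3, :] = [0.003, -0.001]
    kf = MotionKeyframes(t_ph, D, 1.0)
    lz = LandingZone(indices=np.arange(10, 30), ref_positions=wall.X[10:30].copy())
    assert valve_rigid_motion(kf, lz, 0.0).angle == pytest.approx(0.0, abs=1e-14)
    tr = valve_rigid_motion(kf, lz, 0.25)
    assert np.allclose(tr.translation, [0.003, -0.001], atol=1e-14)
    assert tr.angle == pytest.approx(0.0, abs=1e-12)
    # rigidity of the applied motion: pairwise distances preserved
    pts = np.array([[0.0, 0.0], [0.01, 0.0], [0.0, 0.02]])
    moved = tr.apply(pts)
    d0 = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    d1 = np.linalg.norm(moved[:, None] - moved[None], axis=2)
    assert np.max(np.abs(d0 - d1)) <= 1e-12
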