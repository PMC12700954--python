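"""Delta-kernel and spread/interpolate transfer-pair properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ibvalve.kernels as K
from ibvalve.grid import EulerianGrid
from ibvalve.kernels import interpolate, kernel_weight, spread


def test_kernel_closed_form_values():
    assert kernel_weight(0.0) == pytest.approx(0.75)
    assert kernel_weight(1.0) == pytest.approx(0.125)
    assert kernel_weight(0.5) == pytest.approx(0.5)
    assert kernel_weight(1.5) == 0.0
    assert kernel_weight(-1.0) == pytest.approx(0.125)


def test_kernel_support_is_exactly_three_cells():
    r = np.linspace(-3, 3, 1201)
    w = kernel_weight(r)
    assert np.all(w[np.abs(r) > 1.5] == 0.0)
    inside = np.abs(r) < 1.5
    assert np.all(w[inside] > 0.0)


@settings(max_examples=50, deadline=None)
@given(st.floats(-10, 10, allow_nan=False))
def test_kernel_partition_of_unity_and_first_moment(x):
    """Sum over the integer lattice reproduces constants and linear fields."""
    base = np.floor(x)
    nodes = base + np.arange(-2, 4)
    w = kernel_weight(x - nodes)
    assert np.sum(w) == pytest.approx(1.0, abs=1e-12)
    assert np.sum(w * nodes) == pytest.approx(x, abs=1e-12)


def test_kernel_moments_at_many_random_offsets(rng):
    x = rng.uniform(-5, 5, 1000)
    nodes = np.floor(x)[:, None] + np.arange(-2, 4)[None, :]
    w = kernel_weight(x[:, None] - nodes)
    assert np.max(np.abs(w.sum(axis=1) - 1.0)) <= 1e-12
    assert np.max(np.abs((w * nodes).sum(axis=1) - x)) <= 1e-12


@pytest.fixture()
def grid():
    return EulerianGrid(32, 24, 0.01)


@pytest.fixture()
def cloud(grid, rng):
    n = 40
    pts = np.column_stack(
        [rng.uniform(0.05, 0.27, n), rng.uniform(0.05, 0.19, n)]
    )
    w = rng.uniform(2e-3, 8e-3, n)
    return pts, w


def test_spread_conserves_total_force(grid, cloud, rng):
    pts, w = cloud
    F = rng.standard_normal((len(pts), 2))
    fu, fv = spread(F, pts, w, grid)
    total_grid = np.array([fu.sum(), fv.sum()]) * grid.h**2
    total_lag = (F * w[:, None]).sum(axis=0)
    assert np.allclose(total_grid, total_lag, rtol=1e-12, atol=1e-15)


def test_spread_interpolate_adjointness(grid, cloud, rng):
    pts, w = cloud
    F = rng.standard_normal((len(pts), 2))
    u = rng.standard_normal(grid.u_shape)
    v = rng.standard_normal(grid.v_shape)
    fu, fv = spread(F, pts, w, grid)
    lhs = (fu * u).sum() * grid.h**2 + (fv * v).sum() * grid.h**2
    U = interpolate(u, v, pts, grid)
    rhs = (F * U * w[:, None]).sum()
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_interpolate_reproduces_uniform_and_linear_fields(grid, cloud):
    pts, _ = cloud
    u1 = np.ones(grid.u_shape)
    v0 = np.zeros(grid.v_shape)
    U = interpolate(u1, v0, pts, grid)
    assert np.allclose(U[:, 0], 1.0, atol=1e-12)
    assert np.allclose(U[:, 1], 0.0, atol=1e-15)
    # linear field u_x = a*x sampled on the face lattice
    a = 3.7
    xu = grid.u_origin[0] + np.arange(grid.u_shape[0]) * grid.h
    u_lin = np.repeat(a * xu[:, None], grid.u_shape[1], axis=1)
    U = interpolate(u_lin, v0, pts, grid)
    assert np.allclose(U[:, 0], a * pts[:, 0], atol=1e-12)


def test_point_near_boundary_rejected(grid):
    pts = np.array([[grid.h, 0.1]])  # within 1.5 h of the left boundary
    with pytest.raises(ValueError, match="kernel support"):
        spread(np.ones((1, 2)), pts, np.ones(1), grid)
    with pytest.raises(ValueError, match="kernel support"):
        interpolate(np.zeros(grid.u_shape), np.zeros(grid.v_shape), pts, grid)


def test_clamped_transfer_keeps_conservation_and_adjointness(grid, rng):
    """Points sitting on the boundary: clamped stencils stay conservative
    and the transfer pair stays adjoint."""
    pts = np.array([[0.0, 0.12], [0.32, 0.05], [0.16, 0.0], [0.005, 0.002]])
    w = rng.uniform(1e-3, 3e-3, len(pts))
    F = rng.standard_normal((len(pts), 2))
    fu, fv = spread(F, pts, w, grid, clamp=True)
    assert fu.sum() * grid.h**2 == pytest.approx((F[:, 0] * w).sum(), rel=1e-12)
    u = rng.standard_normal(grid.u_shape)
    v = rng.standard_normal(grid.v_shape)
    lhs = (fu * u).sum() * grid.h**2 + (fv * v).sum() * grid.h**2
    U = interpolate(u, v, pts, grid, clamp=True)
    assert lhs == pytest.approx((F * U * w[:, None]).sum(), rel=1e-12)


def test_numba_and_numpy_paths_agree(grid, cloud, rng):
    if not K._HAVE_NUMBA:
        pytest.skip("numba not available; only one path exists")
    pts, w = cloud
    F = rng.standard_normal((len(pts), 2))
    u = rng.standard_normal(grid.u_shape)
    v = rng.standard_normal(grid.v_shape)
    fu1, fv1 = spread(F, pts, w, grid)
    U1 = interpolate(u, v, pts, grid)
    K._HAVE_NUMBA = False
    try:
        fu2, fv2 = spread(F, pts, w, grid)
        U2 = interpolate(u, v, pts, grid)
    finally:
        K._HAVE_NUMBA = True
    assert np.array_equal(fu1, fu2) and np.array_equal(fv1, fv2)
    assert np.allclose(U1, U2, atol=1e-15)
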