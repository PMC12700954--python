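"""Hemodynamic metrics: cloud pressure drop, dissipation, masks, cycles."""

import numpy as np
import pytest

from ibvalve.grid import EulerianGrid
from ibvalve.metrics import (
    SampleClouds,
    disc_cloud,
    energy_loss,
    interior_mask,
    power_loss,
    pressure_drop,
    rate_of_deformation,
    structure_band_mask,
)
from ibvalve.units import MMHG


@pytest.fixture()
def grid():
    return EulerianGrid(64, 48, 0.01)


@pytest.fixture()
def clouds():
    return SampleClouds(lv=disc_cloud((0.15, 0.24), 0.02), aorta=disc_cloud((0.45, 0.24), 0.02))


def test_cloud_size_enforced():
    with pytest.raises(ValueError, match="exactly 20"):
        SampleClouds(lv=np.zeros((19, 2)), aorta=np.zeros((20, 2)))
    assert disc_cloud((0, 0), 1.0).shape == (20, 2)


def test_pressure_drop_uniform_field_is_zero(grid, clouds):
    p = np.full(grid.p_shape, 1234.5)
    assert pressure_drop(p, clouds, grid) == pytest.approx(0.0, abs=1e-12)


def test_pressure_drop_linear_field_exact(grid, clouds):
    """Bilinear interpolation is exact on linear fields: dp = a*(x1 - x2)."""
    a = 700.0
    X, _ = grid.cell_centers()
    p = a * X
    expect = a * (clouds.lv[:, 0].mean() - clouds.aorta[:, 0].mean()) / MMHG
    assert pressure_drop(p, clouds, grid) == pytest.approx(expect, abs=1e-12)


def test_pressure_drop_rejects_point_outside_mask(grid, clouds):
    mask = np.ones(grid.p_shape, dtype=bool)
    mask[:20, :] = False  # LV cloud region marked solid
    with pytest.raises(ValueError, match="lv cloud point"):
        pressure_drop(np.zeros(grid.p_shape), clouds, grid, mask=mask)


def _face_fields(grid, fx, fy):
    xu = grid.u_origin[0] + np.arange(grid.u_shape[0]) * grid.h
    yu = grid.u_origin[1] + np.arange(grid.u_shape[1]) * grid.h
    xv = grid.v_origin[0] + np.arange(grid.v_shape[0]) * grid.h
    yv = grid.v_origin[1] + np.arange(grid.v_shape[1]) * grid.h
    u = fx(xu[:, None], yu[None, :]) * np.ones(grid.u_shape)
    v = fy(xv[:, None], yv[None, :]) * np.ones(grid.v_shape)
    return u, v


def test_rate_of_deformation_rigid_rotation_vanishes(grid):
    w = 3.0
    u, v = _face_fields(grid, lambda x, y: -w * (y - 0.2), lambda x, y: w * (x - 0.3))
    s11, s22, s12 = rate_of_deformation(u, v, grid)
    for s in (s11, s22, s12):
        assert np.max(np.abs(s)) <= 1e-12 * w / grid.h


def test_rate_of_deformation_simple_shear(grid):
    gam = 2.5
    u, v = _face_fields(grid, lambda x, y: gam * y, lambda x, y: 0.0 * x)
    s11, s22, s12 = rate_of_deformation(u, v, grid)
    assert np.max(np.abs(s11)) <= 1e-12
    assert np.max(np.abs(s22)) <= 1e-12
    assert np.allclose(s12, gam / 2, atol=1e-10)


def test_rate_of_deformation_uniform_translation(grid):
    u = np.full(grid.u_shape, 0.7)
    v = np.full(grid.v_shape, -0.2)
    for s in rate_of_deformation(u, v, grid):
        assert np.max(np.abs(s)) == 0.0


def test_power_loss_simple_shear_analytic(grid):
    """P_loss over area A at shear rate gamma equals mu * gamma^2 * A."""
    gam, mu = 2.5, 0.03
    u, v = _face_fields(grid, lambda x, y: gam * y, lambda x, y: 0.0 * x)
    mask = np.ones(grid.p_shape, dtype=bool)
    A = mask.sum() * grid.h**2
    assert power_loss(u, v, mask, mu, grid) == pytest.approx(mu * gam**2 * A, rel=0.01)


def test_power_loss_rigid_rotation_negligible(grid):
    w, mu = 2.5, 0.03
    u, v = _face_fields(grid, lambda x, y: -w * (y - 0.2), lambda x, y: w * (x - 0.3))
    mask = np.ones(grid.p_shape, dtype=bool)
    us, vs = _face_fields(grid, lambda x, y: w * y, lambda x, y: 0.0 * x)
    shear_ref = power_loss(us, vs, mask, mu, grid)
    assert power_loss(u, v, mask, mu, grid) <= 1e-12 * shear_ref


def test_power_loss_poiseuille_closed_form():
    """Parabolic profile of peak U0 over gap H and length l dissipates
    (16/3) mu U0^2 l / H per unit depth."""
    grid = EulerianGrid(64, 64, 1.0 / 64)
    H, U0, mu = 1.0, 1.5, 0.07
    yu = grid.u_origin[1] + np.arange(grid.u_shape[1]) * grid.h
    u = np.tile(4 * U0 * yu * (H - yu) / H**2, (grid.u_shape[0], 1))
    v = np.zeros(grid.v_shape)
    mask = np.ones(grid.p_shape, dtype=bool)
    ell = grid.nx * grid.h
    expect = (16.0 / 3.0) * mu * U0**2 * ell / H
    assert power_loss(u, v, mask, mu, grid) == pytest.approx(expect, rel=0.02)


def test_power_loss_empty_mask_rejected(grid):
    with pytest.raises(ValueError, match="empty"):
        power_loss(np.zeros(grid.u_shape), np.zeros(grid.v_shape),
                   np.zeros(grid.p_shape, bool), 1.0, grid)


def test_energy_loss_trapezoid_cases():
    t = np.linspace(0.0, 2.0, 401)
    assert energy_loss(t, np.full_like(t, 3.0), 0.5, 1.5) == pytest.approx(3.0)
    assert energy_loss(t, np.zeros_like(t), 0.0, 2.0) == 0.0
    ramp = 5.0 * t / 2.0
    assert energy_loss(t, ramp, 0.0, 2.0) == pytest.approx(5.0 * 2.0 / 2.0, abs=1e-12)
    with pytest.raises(ValueError, match="not fully covered"):
        energy_loss(t, ramp, 1.5, 3.0)


def test_interior_mask_square_circle_and_outside_point():
    grid = EulerianGrid(128, 128, 1.0 / 128)
    s = 0.5
    sq = np.array([[0.25, 0.25], [0.75, 0.25], [0.75, 0.75], [0.25, 0.75]])
    m = interior_mask(sq, grid)
    assert m.sum() * grid.h**2 == pytest.approx(s**2, abs=2 * 4 * s * grid.h)
    # point far outside
    i, j = 5, 5
    assert not m[i, j]
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    R = 0.35
    circ = np.column_stack([0.5 + R * np.cos(th), 0.5 + R * np.sin(th)])
    mc = interior_mask(circ, grid)
    assert mc.sum() * grid.h**2 == pytest.approx(np.pi * R**2, rel=0.03)
    with pytest.raises(ValueError):
        interior_mask(sq[:2], grid)


def test_structure_band_mask_covers_kernel_width(grid):
    pts = np.array([[0.3, 0.25]])
    band = structure_band_mask(pts, grid, 1.5 * grid.h)
    X, Y = grid.cell_centers()
    d = np.hypot(X - 0.3, Y - 0.25)
    assert np.array_equal(band, d <= 1.5 * grid.h)
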