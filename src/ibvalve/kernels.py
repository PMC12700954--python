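"""Regularized delta-function kernel and the spread/interpolate transfer pair.

The Lagrangian-Eulerian coupling uses a three-point quadratic B-spline kernel,
phi(r) = 3/4 - r^2              for |r| <= 1/2
       = (3/2 - |r|)^2 / 2      for 1/2 < |r| <= 3/2
       = 0                      otherwise,
which satisfies the partition of unity and the zero-first-moment condition
(exact reproduction of constant and linear fields under interpolation).

`spread` and `interpolate` are exact adjoints of each other with respect to
the discrete inner products sum(f*u)*h^2 (grid) and sum(F*U*w) (structure).
"""

from __future__ import annotations

import numpy as np

try:  # optional acceleration; the numpy path below is the reference
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False

#: half-width of the kernel support in cells
KERNEL_SUPPORT = 1.5


def kernel_weight(r):
    """Three-point quadratic B-spline kernel, vectorized over r."""
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    inner = r <= 0.5
    outer = (r > 0.5) & (r <= 1.5)
    out[inner] = 0.75 - r[inner] ** 2
    out[outer] = 0.5 * (1.5 - r[outer]) ** 2
    return out if out.ndim else float(out)


def _stencil(coords: np.ndarray, origin: float, h: float):
    """Return (indices, weights) of the 3-node kernel stencil per point.

    coords : (n,) physical coordinates along one axis
    origin : physical coordinate of node index 0

    The three weights are the closed-form B-spline values at offsets
    f-1, f, f+1 with f = g - round(g) in [-1/2, 1/2].
    """
    g = (coords - origin) / h
    base = np.rint(g).astype(int)
    idx = base[:, None] + np.array([-1, 0, 1])[None, :]
    f = g - base
    w = np.empty((len(g), 3))
    w[:, 0] = 0.5 * (0.5 - f) ** 2
    w[:, 1] = 0.75 - f**2
    w[:, 2] = 0.5 * (0.5 + f) ** 2
    return idx, w


def _check_interior(points: np.ndarray, grid) -> None:
    x0, x1, y0, y1 = grid.extent
    m = KERNEL_SUPPORT * grid.h
    bad = (
        (points[:, 0] < x0 + m)
        | (points[:, 0] > x1 - m)
        | (points[:, 1] < y0 + m)
        | (points[:, 1] > y1 - m)
    )
    if np.any(bad):
        q = int(np.argmax(bad))
        raise ValueError(
            f"structure point {q} at {points[q]} is within {KERNEL_SUPPORT} h "
            "of the domain boundary; kernel support would be clipped"
        )


if _HAVE_NUMBA:

    @njit(fastmath=False)
    def _jit_transfer(field_shape0, field_shape1, pts, ox, oy, h, vals, mode_spread, field):
        """Shared scatter/gather core with clamped 3-point stencils.

        mode_spread: scatter vals onto field (in place); else gather field at
        the points into vals (out).
        """
        n = pts.shape[0]
        for q in range(n):
            gx = (pts[q, 0] - ox) / h
            gy = (pts[q, 1] - oy) / h
            bx = int(np.rint(gx))
            by = int(np.rint(gy))
            fx = gx - bx
            fy = gy - by
            wx0 = 0.5 * (0.5 - fx) ** 2
            wx1 = 0.75 - fx * fx
            wx2 = 0.5 * (0.5 + fx) ** 2
            wy0 = 0.5 * (0.5 - fy) ** 2
            wy1 = 0.75 - fy * fy
            wy2 = 0.5 * (0.5 + fy) ** 2
            acc = 0.0
            for a in range(3):
                ia = bx - 1 + a
                if ia < 0:
                    ia = 0
                elif ia > field_shape0 - 1:
                    ia = field_shape0 - 1
                wa = wx0 if a == 0 else (wx1 if a == 1 else wx2)
                for b in range(3):
                    jb = by - 1 + b
                    if jb < 0:
                        jb = 0
                    elif jb > field_shape1 - 1:
                        jb = field_shape1 - 1
                    wb = wy0 if b == 0 else (wy1 if b == 1 else wy2)
                    if mode_spread:
                        field[ia, jb] += vals[q] * wa * wb
                    else:
                        acc += field[ia, jb] * wa * wb
            if not mode_spread:
                vals[q] = acc


def _transfer_fast(points, grid, vals_u, vals_v, spread_mode, fu, fv):
    _jit_transfer(
        grid.u_shape[0], grid.u_shape[1], points, grid.u_origin[0], grid.u_origin[1],
        grid.h, vals_u, spread_mode, fu,
    )
    _jit_transfer(
        grid.v_shape[0], grid.v_shape[1], points, grid.v_origin[0], grid.v_origin[1],
        grid.h, vals_v, spread_mode, fv,
    )


def spread(F: np.ndarray, points: np.ndarray, weights: np.ndarray, grid, clamp: bool = False):
    """Spread Lagrangian force density F [Pa per unit length] to grid faces.

    Returns (fu, fv), Eulerian force density [N/m^3] on the u- and v-faces.
    Total force is conserved: sum(fu)*h^2 == sum(F[:,0]*weights), same for v.

    With `clamp=True`, points may approach (or sit on) the domain boundary:
    stencil indices are clamped so weight that would fall outside is deposited
    on the boundary-adjacent nodes. Conservation and the spread/interpolate
    adjointness are preserved exactly; intended for structures sealed against
    a solid outer boundary. The default rejects points within 1.5 h.
    """
    if not clamp:
        _check_interior(points, grid)
    if _HAVE_NUMBA:
        fu = np.zeros(grid.u_shape)
        fv = np.zeros(grid.v_shape)
        scale = weights / grid.h**2
        pts = np.ascontiguousarray(points)
        _transfer_fast(pts, grid, np.ascontiguousarray(F[:, 0] * scale),
                       np.ascontiguousarray(F[:, 1] * scale), True, fu, fv)
        return fu, fv
    out = []
    scale = weights / grid.h**2
    for shape, comp, (ox, oy) in (
        (grid.u_shape, 0, grid.u_origin),
        (grid.v_shape, 1, grid.v_origin),
    ):
        ix, wx = _stencil(points[:, 0], ox, grid.h)
        iy, wy = _stencil(points[:, 1], oy, grid.h)
        if clamp:
            ix = np.clip(ix, 0, shape[0] - 1)
            iy = np.clip(iy, 0, shape[1] - 1)
        flat = (ix[:, :, None] * shape[1] + iy[:, None, :]).ravel()
        vals = ((F[:, comp] * scale)[:, None, None] * wx[:, :, None] * wy[:, None, :]).ravel()
        out.append(
            np.bincount(flat, weights=vals, minlength=shape[0] * shape[1]).reshape(shape)
        )
    return out[0], out[1]


def interpolate(
    u: np.ndarray, v: np.ndarray, points: np.ndarray, grid, clamp: bool = False
) -> np.ndarray:
    """Interpolate the face velocity field to structure points.

    Exact for constant and linear velocity fields (kernel moment conditions).
    `clamp` mirrors the spread option (shared index map keeps adjointness).
    """
    if not clamp:
        _check_interior(points, grid)
    out = np.zeros((len(points), 2))
    if _HAVE_NUMBA:
        pts = np.ascontiguousarray(points)
        vals_u = np.zeros(len(points))
        vals_v = np.zeros(len(points))
        _transfer_fast(pts, grid, vals_u, vals_v, False,
                       np.ascontiguousarray(u), np.ascontiguousarray(v))
        out[:, 0] = vals_u
        out[:, 1] = vals_v
        return out
    for comp, field, (ox, oy) in ((0, u, grid.u_origin), (1, v, grid.v_origin)):
        ix, wx = _stencil(points[:, 0], ox, grid.h)
        iy, wy = _stencil(points[:, 1], oy, grid.h)
        if clamp:
            ix = np.clip(ix, 0, field.shape[0] - 1)
            iy = np.clip(iy, 0, field.shape[1] - 1)
        g = field[ix[:, :, None], iy[:, None, :]]  # (n, 3, 3)
        out[:, comp] = np.einsum("nab,na,nb->n", g, wx, wy)
    return out
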