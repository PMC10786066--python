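"""Numba-jitted overdamped Langevin integrator kernels.

The integrators advance an overdamped Euler–Maruyama scheme,

    x_{t+1} = x_t - dt/gamma * dU/dx + sqrt(2 kT dt / gamma) * xi_t,

on an analytic potential plus an optional bias evaluated from a cached grid
(linear interpolation of a precomputed bias-force table). Normals are drawn
outside the kernel so seeding stays in one place.

Potential form codes: 0 = flat (reflecting walls), 1 = harmonic(k),
2 = double well h*(x^2-1)^2 + tilt*x.
"""

from __future__ import annotations

import numpy as np
from numba import njit

FORM_FLAT = 0
FORM_HARMONIC = 1
FORM_DOUBLE_WELL = 2


@njit(cache=False)
def _force_1d(x, form, h, k, tilt):
    if form == FORM_HARMONIC:
        return -k * x
    if form == FORM_DOUBLE_WELL:
        return -(4.0 * h * x * (x * x - 1.0) + tilt)
    return 0.0


@njit(cache=False)
def _interp(grid, gmin, inv_dx, x):
    """Clamped linear interpolation on a uniform grid."""
    n = grid.shape[0]
    t = (x - gmin) * inv_dx
    if t <= 0.0:
        return grid[0]
    if t >= n - 1:
        return grid[n - 1]
    i = int(t)
    f = t - i
    return grid[i] * (1.0 - f) + grid[i + 1] * f


@njit(cache=False)
def integrate_1d(x0, normals, dt, kT, friction, form, h, k, tilt,
                 lo, hi, reflect, bias_v, bias_f, gmin, inv_dx,
                 out_x, out_bias):
    """Advance len(normals) steps from x0; fill positions and applied bias.

    Returns (status, x_final): status 0 ok, 1 diverged.
    """
    n = normals.shape[0]
    x = x0
    amp = np.sqrt(2.0 * kT * dt / friction)
    use_bias = bias_v.shape[0] > 1
    for i in range(n):
        f = _force_1d(x, form, h, k, tilt)
        if use_bias:
            f += _interp(bias_f, gmin, inv_dx, x)
        x = x + dt / friction * f + amp * normals[i]
        if reflect:
            # fold back into [lo, hi]
            while x < lo or x > hi:
                if x < lo:
                    x = 2.0 * lo - x
                if x > hi:
                    x = 2.0 * hi - x
        if not np.isfinite(x) or x > 1e6 or x < -1e6:
            return 1, x
        out_x[i] = x
        if use_bias:
            out_bias[i] = _interp(bias_v, gmin, inv_dx, x)
        else:
            out_bias[i] = 0.0
    return 0, x


@njit(cache=False)
def _interp2(grid, gxmin, inv_dx, gymin, inv_dy, x, y):
    nx = grid.shape[0]
    ny = grid.shape[1]
    tx = (x - gxmin) * inv_dx
    ty = (y - gymin) * inv_dy
    if tx < 0.0:
        tx = 0.0
    if tx > nx - 1.000001:
        tx = nx - 1.000001
    if ty < 0.0:
        ty = 0.0
    if ty > ny - 1.000001:
        ty = ny - 1.000001
    i = int(tx)
    j = int(ty)
    fx = tx - i
    fy = ty - j
    return (grid[i, j] * (1 - fx) * (1 - fy) + grid[i + 1, j] * fx * (1 - fy)
            + grid[i, j + 1] * (1 - fx) * fy + grid[i + 1, j + 1] * fx * fy)


@njit(cache=False)
def integrate_2d(x0, y0, normals, dt, kT, friction, h, ky, tilt,
                 bias_v, bias_fx, bias_fy, gxmin, inv_dx, gymin, inv_dy,
                 out_xy, out_bias):
    """2-D double well h*(x^2-1)^2 + 0.5*ky*y^2 + tilt*x with optional bias."""
    n = normals.shape[0]
    x = x0
    y = y0
    amp = np.sqrt(2.0 * kT * dt / friction)
    use_bias = bias_v.shape[0] > 1
    for i in range(n):
        fx = -(4.0 * h * x * (x * x - 1.0) + tilt)
        fy = -ky * y
        if use_bias:
            fx += _interp2(bias_fx, gxmin, inv_dx, gymin, inv_dy, x, y)
            fy += _interp2(bias_fy, gxmin, inv_dx, gymin, inv_dy, x, y)
        x = x + dt / friction * fx + amp * normals[i, 0]
        y = y + dt / friction * fy + amp * normals[i, 1]
        if not (np.isfinite(x) and np.isfinite(y)) or abs(x) > 1e6 or abs(y) > 1e6:
            return 1, x, y
        out_xy[i, 0] = x
        out_xy[i, 1] = y
        if use_bias:
            out_bias[i] = _interp2(bias_v, gxmin, inv_dx, gymin, inv_dy, x, y)
        else:
            out_bias[i] = 0.0
    return 0, x, y
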