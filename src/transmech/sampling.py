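"""Coordination-number CVs and an OPES-Explore bias engine.

The coordination CV sums a rational switching function

    s(r) = (1 - x^n) / (1 - x^m),   x = max(r - d0, 0) / r0,

over partner distances (the removable singularity at x = 1 evaluates to
n/m). Defaults follow the vestibule-water CV (r0 = 8.0 A, d0 = 0, n = 2,
m = 8); ion-site coordination uses the same form with r0 = 2.35 A.

The bias engine implements the *Explore* flavor of on-the-fly probability
enhanced sampling: Gaussian kernels are deposited on the sampled (biased)
marginal every ``stride`` steps, the bias is

    V(s) = (gamma - 1) kT ln( p(s)/Z + eps ),  eps = exp(-dE / ((gamma-1) kT)),

shifted to zero in unexplored regions and clipped at the barrier parameter
dE, with gamma = dE / kT. Free-energy surfaces are recovered from biased
runs by kernel (or histogram) reweighting with weights exp(V_t / kT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _integrators
from .core import Frame
from .synthetic import PotentialSpec

__all__ = [
    "KB_KCAL", "kT_at",
    "SwitchingParams", "CoordinationCVSpec", "OPESConfig", "BiasState",
    "rational_switch", "coordination_cv",
    "opes_update", "opes_bias", "reweight_fes", "run_opes_langevin",
]

KB_KCAL = 0.0019872041  # kcal/mol/K


def kT_at(temperature: float = 310.0) -> float:
    return KB_KCAL * temperature


@dataclass
class SwitchingParams:
    """Rational switching function parameters (lengths in A)."""

    r0: float = 8.0
    d0: float = 0.0
    n: int = 2
    m: int = 8

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 < self.n < self.m):
            raise ValueError("require m > n > 0")


# Ion-site coordination parameters (same rational form, tighter radius).
ION_SITE_SWITCH = SwitchingParams(r0=2.35, d0=0.0, n=2, m=8)


def rational_switch(r, p: SwitchingParams):
    """Evaluate s(r) elementwise; total over r >= 0, in [0, 1]."""
    r = np.asarray(r, dtype=float)
    x = np.maximum(r - p.d0, 0.0) / p.r0
    xn = x ** p.n
    xm = x ** p.m
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (1.0 - xn) / (1.0 - xm)
    # removable singularity at x = 1: limit is n/m
    s = np.where(np.isclose(x, 1.0, rtol=0.0, atol=1e-12), p.n / p.m, s)
    return s if s.ndim else float(s)


@dataclass
class CoordinationCVSpec:
    """Coordination number of ``partners`` around a fixed virtual point or
    an atom selection center."""

    center: np.ndarray                     # (3,) virtual point, A
    partners: np.ndarray                   # atom indices
    params: SwitchingParams = field(default_factory=SwitchingParams)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.partners = np.asarray(self.partners, dtype=int)
        if self.partners.size == 0:
            raise ValueError("partners must be nonempty")


def coordination_cv(frame: Frame, spec: CoordinationCVSpec) -> float:
    """Sum of the switching function over partner distances to the center."""
    d = np.linalg.norm(frame.coords[spec.partners] - spec.center, axis=1)
    return float(np.sum(rational_switch(d, spec.params)))


# ---------------------------------------------------------------------------
# OPES Explore
# ---------------------------------------------------------------------------

@dataclass
class OPESConfig:
    """OPES-Explore settings (energies kcal/mol, temperature K).

    Defaults mirror the conformational-sampling setup: 20 kcal/mol barrier,
    one kernel every 500 steps, 310 K, initial sigma 0.1 / 0.3 and minimum
    sigma 0.05 / 0.15 for the two CVs. ``bias_factor`` defaults to
    barrier / kT.
    """

    barrier: float = 20.0
    stride: int = 500
    temperature: float = 310.0
    sigma_initial: tuple[float, ...] = (0.1, 0.3)
    sigma_min: tuple[float, ...] = (0.05, 0.15)
    adaptive: bool = True
    bias_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise ValueError("barrier must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if any(m > s for s, m in zip(self.sigma_initial, self.sigma_min)):
            raise ValueError("sigma_min must be <= sigma_initial componentwise")

    @property
    def kT(self) -> float:
        return kT_at(self.temperature)

    @property
    def gamma(self) -> float:
        return self.bias_factor if self.bias_factor is not None else self.barrier / self.kT


class BiasState:
    """Deposited OPES kernels and the derived bias potential.

    The bias is zero where nothing has been deposited, grows where sampling
    has accumulated, and is clipped at the barrier parameter, so its range
    never exceeds the configured barrier.
    """

    def __init__(self, cfg: OPESConfig, ndim: int = 1):
        self.cfg = cfg
        self.ndim = ndim
        self.centers = np.zeros((0, ndim))
        self.bandwidths = np.zeros((0, ndim))
        self.heights = np.zeros(0)
        # running sums of the KDE evaluated at every kernel center, for the
        # normalization Z = mean_i p(s_i) maintained incrementally
        self._m = np.zeros(0)

    @property
    def n_kernels(self) -> int:
        return len(self.heights)

    @property
    def z_norm(self) -> float:
        if self.n_kernels == 0:
            return 1.0
        return float(self._m.mean() / self.n_kernels)

    def kde(self, points: np.ndarray) -> np.ndarray:
        """Unnormalized-mean KDE of deposited kernels at ``points``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.n_kernels == 0:
            return np.zeros(len(pts))
        d2 = ((pts[:, None, :] - self.centers[None, :, :])
              / self.bandwidths[None, :, :]) ** 2
        g = self.heights[None, :] * np.exp(-0.5 * d2.sum(axis=2))
        return g.sum(axis=1) / self.n_kernels

    def bias(self, points: np.ndarray) -> np.ndarray:
        """Bias potential (kcal/mol) at CV-space points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cfg = self.cfg
        if self.n_kernels == 0:
            return np.zeros(len(pts))
        gamma = cfg.gamma
        eps = np.exp(-cfg.barrier / ((gamma - 1.0) * cfg.kT))
        p_over_z = self.kde(pts) / self.z_norm
        v = (gamma - 1.0) * cfg.kT * (np.log(p_over_z + eps) - np.log(eps))
        return np.minimum(v, cfg.barrier)

    def current_sigma(self) -> np.ndarray:
        """Bandwidth for the next kernel: shrink the sampled SD with the
        kernel count, floored at sigma_min."""
        cfg = self.cfg
        s0 = np.array(cfg.sigma_initial[: self.ndim], dtype=float)
        smin = np.array(cfg.sigma_min[: self.ndim], dtype=float)
        if not cfg.adaptive or self.n_kernels < 10:
            return np.maximum(s0, smin)
        sd = self.centers.std(axis=0, ddof=1)
        return np.maximum(smin, sd / np.sqrt(self.n_kernels))

    def add_kernel(self, point: np.ndarray) -> None:
        point = np.atleast_1d(np.asarray(point, dtype=float))
        if not np.all(np.isfinite(point)):
            raise RuntimeError("non-finite CV point passed to OPES update")
        sigma = self.current_sigma()
        height = 1.0 / (np.power(2 * np.pi, self.ndim / 2) * np.prod(sigma))
        # update the running center-KDE sums before appending: existing
        # centers gain the new kernel (its own bandwidth), the new center
        # collects all old kernels (their bandwidths) plus its self term
        if self.n_kernels:
            d2_at_old = (((self.centers - point) / sigma) ** 2).sum(axis=1)
            self._m += height * np.exp(-0.5 * d2_at_old)
            d2_at_new = (((point - self.centers) / self.bandwidths) ** 2).sum(axis=1)
            m_new = height + np.sum(self.heights * np.exp(-0.5 * d2_at_new))
        else:
            m_new = height
        self.centers = np.vstack([self.centers, point])
        self.bandwidths = np.vstack([self.bandwidths, sigma])
        self.heights = np.append(self.heights, height)
        self._m = np.append(self._m, m_new)


def opes_update(state: BiasState, cv_point, cfg: Optional[OPESConfig] = None
                ) -> BiasState:
    """Deposit one kernel at ``cv_point`` (call every ``stride`` steps)."""
    if cfg is not None and cfg is not state.cfg:
        state.cfg = cfg
    state.add_kernel(cv_point)
    return state


def opes_bias(state: BiasState, cv_point) -> float | np.ndarray:
    """Bias energy at one or more CV points; zero with no kernels."""
    pts = np.asarray(cv_point, dtype=float)
    scalar = pts.ndim == 0 or (state.ndim > 1 and pts.ndim == 1)
    out = state.bias(pts.reshape(-1, state.ndim))
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Reweighting
# ---------------------------------------------------------------------------

def reweight_fes(cv_series: np.ndarray, bias_series: np.ndarray, kT: float,
                 grid: np.ndarray, kernel_width: float = 0.0,
                 burn_in_fraction: float = 0.0) -> np.ndarray:
    """Free energy on ``grid`` from a biased CV series.

    F(z) = -kT ln sum_t w_t K(z - s_t), w_t = exp(bias_t / kT), min-shifted
    to zero. ``kernel_width`` 0 selects histogram binning at the grid
    resolution; positive values use a Gaussian kernel of that width. 2-D
    grids are passed as a tuple of axes with cv_series shaped (n, 2).
    """
    cv = np.asarray(cv_series, dtype=float)
    bias = np.asarray(bias_series, dtype=float)
    if cv.shape[0] == 0:
        raise ValueError("empty CV series")
    if cv.shape[0] != bias.shape[0]:
        raise ValueError("cv and bias series must be aligned")
    start = int(burn_in_fraction * cv.shape[0])
    cv, bias = cv[start:], bias[start:]
    logw = (bias - bias.max()) / kT
    w = np.exp(logw)

    if isinstance(grid, tuple):
        gx, gy = (np.asarray(g) for g in grid)
        if kernel_width > 0:
            kx = np.exp(-0.5 * ((gx[:, None] - cv[None, :, 0]) / kernel_width) ** 2)
            ky = np.exp(-0.5 * ((gy[:, None] - cv[None, :, 1]) / kernel_width) ** 2)
            dens = np.einsum("it,jt,t->ij", kx, ky, w)
        else:
            ex = np.concatenate([gx - 0.5 * (gx[1] - gx[0]), [gx[-1] + 0.5 * (gx[1] - gx[0])]])
            ey = np.concatenate([gy - 0.5 * (gy[1] - gy[0]), [gy[-1] + 0.5 * (gy[1] - gy[0])]])
            dens, _, _ = np.histogram2d(cv[:, 0], cv[:, 1], bins=(ex, ey), weights=w)
        with np.errstate(divide="ignore"):
            f = -kT * np.log(dens)
        return f - np.nanmin(f[np.isfinite(f)])

    grid = np.asarray(grid, dtype=float)
    if kernel_width > 0:
        kern = np.exp(-0.5 * ((grid[:, None] - cv[None, :]) / kernel_width) ** 2)
        dens = kern @ w
    else:
        half = 0.5 * (grid[1] - grid[0])
        edges = np.concatenate([grid - half, [grid[-1] + half]])
        dens, _ = np.histogram(cv, bins=edges, weights=w)
    with np.errstate(divide="ignore"):
        f = -kT * np.log(dens)
    return f - np.min(f[np.isfinite(f)])


# ---------------------------------------------------------------------------
# Biased Langevin driver
# ---------------------------------------------------------------------------

@dataclass
class OPESRun:
    """Recorded output of a biased Langevin run."""

    times: np.ndarray         # step index * dt
    cv: np.ndarray            # (n_rec,) or (n_rec, 2)
    bias: np.ndarray          # applied bias at each recorded sample
    state: BiasState
    grid: np.ndarray          # bias cache grid (1-D axis or tuple of axes)
    bias_on_grid: np.ndarray  # final bias evaluated on the cache grid


def _bias_from_density(state: BiasState, dens_sum: np.ndarray) -> np.ndarray:
    """Bias on a cache grid from the accumulated kernel-density sum."""
    cfg = state.cfg
    gamma = cfg.gamma
    eps = np.exp(-cfg.barrier / ((gamma - 1.0) * cfg.kT))
    p_over_z = dens_sum / state.n_kernels / state.z_norm
    v = (gamma - 1.0) * cfg.kT * (np.log(p_over_z + eps) - np.log(eps))
    return np.minimum(v, cfg.barrier)


def _force_1d(v: np.ndarray, grid: np.ndarray) -> np.ndarray:
    f = np.zeros_like(v)
    f[1:-1] = -(v[2:] - v[:-2]) / (grid[2] - grid[0])
    f[0] = f[1]
    f[-1] = f[-2]
    return f


def run_opes_langevin(pot: PotentialSpec, cfg: OPESConfig, n_steps: int,
                      dt: float = 0.002, friction: float = 1.0, seed: int = 0,
                      x0=None, record_stride: int = 10,
                      grid_range: tuple[float, float] = (-2.5, 2.5),
                      grid_points: int = 501) -> OPESRun:
    """OPES-Explore-biased overdamped Langevin sampling of a toy potential.

    Kernels are deposited every ``cfg.stride`` steps at the current CV value;
    between depositions the integrator feels the bias through a cached grid
    (linear interpolation). Positions and the applied bias are recorded every
    ``record_stride`` steps for reweighting.
    """
    rng = np.random.default_rng(seed)
    ndim = pot.ndim
    state = BiasState(cfg, ndim=ndim)
    kT = cfg.kT

    if ndim == 1:
        grid = np.linspace(*grid_range, grid_points)
        inv_dx = 1.0 / (grid[1] - grid[0])
        bias_v = np.zeros(1)
        bias_f = np.zeros(1)
        dens_sum = np.zeros(grid_points)   # running sum of kernel densities
        x = float(x0) if x0 is not None else -1.0
        rec_x, rec_b, rec_t = [], [], []
        step = 0
        while step < n_steps:
            chunk = min(cfg.stride, n_steps - step)
            out_x = np.empty(chunk)
            out_b = np.empty(chunk)
            status, x = _integrators.integrate_1d(
                x, rng.standard_normal(chunk), dt, kT, friction,
                pot.form_code(), pot.h, pot.k, pot.tilt,
                pot.bounds[0], pot.bounds[1], pot.form == "flat",
                bias_v, bias_f, grid[0], inv_dx, out_x, out_b)
            if status:
                raise RuntimeError("biased Langevin run diverged; reduce dt")
            rec = np.arange(chunk) % record_stride == record_stride - 1
            rec_x.append(out_x[rec])
            rec_b.append(out_b[rec])
            rec_t.append((step + np.nonzero(rec)[0] + 1) * dt)
            step += chunk
            if step < n_steps or chunk == cfg.stride:
                state.add_kernel(np.array([x]))
                c = state.centers[-1, 0]
                s = state.bandwidths[-1, 0]
                dens_sum = dens_sum + state.heights[-1] * np.exp(
                    -0.5 * ((grid - c) / s) ** 2)
                bias_v = _bias_from_density(state, dens_sum)
                bias_f = _force_1d(bias_v, grid)
        return OPESRun(np.concatenate(rec_t), np.concatenate(rec_x),
                       np.concatenate(rec_b), state, grid, bias_v)

    # 2-D: double well in x, harmonic in y
    gx = np.linspace(*grid_range, min(grid_points, 201))
    gy = np.linspace(-2.5, 2.5, 101)
    inv_dx = 1.0 / (gx[1] - gx[0])
    inv_dy = 1.0 / (gy[1] - gy[0])
    bias_v = np.zeros((1, 1))
    bias_fx = np.zeros((1, 1))
    bias_fy = np.zeros((1, 1))
    dens_sum = np.zeros((len(gx), len(gy)))
    xy = np.asarray(x0, dtype=float) if x0 is not None else np.array([-1.0, 0.0])
    rec_xy, rec_b, rec_t = [], [], []
    step = 0
    while step < n_steps:
        chunk = min(cfg.stride, n_steps - step)
        out_xy = np.empty((chunk, 2))
        out_b = np.empty(chunk)
        status, x_, y_ = _integrators.integrate_2d(
            xy[0], xy[1], rng.standard_normal((chunk, 2)), dt, kT, friction,
            pot.h, pot.ky, pot.tilt,
            bias_v, bias_fx, bias_fy, gx[0], inv_dx, gy[0], inv_dy,
            out_xy, out_b)
        if status:
            raise RuntimeError("biased Langevin run diverged; reduce dt")
        xy = np.array([x_, y_])
        rec = np.arange(chunk) % record_stride == record_stride - 1
        rec_xy.append(out_xy[rec])
        rec_b.append(out_b[rec])
        rec_t.append((step + np.nonzero(rec)[0] + 1) * dt)
        step += chunk
        if step < n_steps or chunk == cfg.stride:
            state.add_kernel(xy)
            cx, cy = state.centers[-1]
            sx, sy = state.bandwidths[-1]
            dens_sum = dens_sum + state.heights[-1] * np.outer(
                np.exp(-0.5 * ((gx - cx) / sx) ** 2),
                np.exp(-0.5 * ((gy - cy) / sy) ** 2))
            v = _bias_from_density(state, dens_sum)
            bias_v = v
            bias_fx = np.zeros_like(v)
            bias_fy = np.zeros_like(v)
            bias_fx[1:-1, :] = -(v[2:, :] - v[:-2, :]) * 0.5 * inv_dx
            bias_fy[:, 1:-1] = -(v[:, 2:] - v[:, :-2]) * 0.5 * inv_dy
            bias_fx[0], bias_fx[-1] = bias_fx[1], bias_fx[-2]
            bias_fy[:, 0], bias_fy[:, -1] = bias_fy[:, 1], bias_fy[:, -2]
    return OPESRun(np.concatenate(rec_t), np.concatenate(rec_xy),
                   np.concatenate(rec_b), state, (gx, gy), bias_v)
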