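"""Free-energy-surface analysis: basin identification, inter-basin barriers
and binding free energies.

Grids are min-normalized free energies (kcal/mol) over one or two CV axes.
Basins are found by persistence-based flood fill: grid points are visited in
ascending energy, connected components grow and merge, and a component
shallower than ``min_depth`` at its merge saddle is absorbed into its deeper
neighbor. Barriers are minimax path heights (the lowest saddle any grid path
must climb over), reported per direction relative to each basin floor.
Basin free energies use the log-sum-exp over the basin's catchment rather
than the bare minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .sampling import kT_at

__all__ = ["FESGrid", "Basin", "BasinSet", "BindingResult",
           "find_basins", "barrier_between", "binding_dg"]


@dataclass
class FESGrid:
    """Free energy on a uniform 1-D or 2-D grid, min-normalized to 0.

    Unsampled points are NaN and excluded from every analysis.
    """

    axes: tuple[np.ndarray, ...]
    F: np.ndarray

    def __post_init__(self) -> None:
        self.axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        self.F = np.asarray(self.F, dtype=float)
        expected = tuple(len(a) for a in self.axes)
        if self.F.shape != expected:
            raise ValueError(f"F shape {self.F.shape} != axes {expected}")
        finite = np.isfinite(self.F)
        if not finite.any():
            raise ValueError("grid has no finite values")
        self.F = self.F - self.F[finite].min()

    @property
    def ndim(self) -> int:
        return self.F.ndim


@dataclass
class Basin:
    label: int
    location: tuple            # grid index of the minimum
    f_min: float
    members: np.ndarray        # flat indices of the catchment


@dataclass
class BasinSet:
    basins: list[Basin]
    barriers: np.ndarray       # (n, n) minimax saddle heights (absolute F)
    grid: FESGrid = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.basins)


def _neighbors(shape):
    """Orthogonal-neighbor offsets for 1-D or 2-D grids."""
    if len(shape) == 1:
        return [(-1,), (1,)]
    return [(-1, 0), (1, 0), (0, -1), (0, 1)]


def find_basins(fes: FESGrid, min_depth: float = 1.0,
                energy_window: Optional[float] = None) -> BasinSet:
    """Persistence flood-fill over the grid.

    A local minimum survives as a basin only if it is separated from any
    deeper minimum by a saddle at least ``min_depth`` above it; shallower
    features are merged. ``energy_window`` (above the global minimum)
    optionally discards high-lying basins.
    """
    F = fes.F
    shape = F.shape
    flat = F.ravel()
    finite = np.isfinite(flat)
    order = np.argsort(np.where(finite, flat, np.inf), kind="stable")
    order = order[: finite.sum()]

    comp = np.full(flat.size, -1)           # point -> component id
    comp_min_idx: list[int] = []            # component -> flat index of its minimum
    parent: dict[int, int] = {}             # merged component -> absorbing component
    saddles: dict[tuple[int, int], float] = {}

    def find(c: int) -> int:
        while parent.get(c, c) != c:
            parent[c] = parent.get(parent[c], parent[c])
            c = parent[c]
        return c

    offs = _neighbors(shape)
    for p in order:
        idx = np.unravel_index(p, shape)
        neighbor_comps = set()
        for off in offs:
            q = tuple(i + o for i, o in zip(idx, off))
            if any(i < 0 or i >= s for i, s in zip(q, shape)):
                continue
            qf = np.ravel_multi_index(q, shape)
            if comp[qf] >= 0:
                neighbor_comps.add(find(comp[qf]))
        if not neighbor_comps:
            comp[p] = len(comp_min_idx)
            comp_min_idx.append(p)
            continue
        # attach to the deepest neighboring component
        target = min(neighbor_comps, key=lambda c: flat[comp_min_idx[c]])
        comp[p] = target
        for c in neighbor_comps:
            if c == target:
                continue
            # c merges into target at saddle height flat[p]
            persistence = flat[p] - flat[comp_min_idx[c]]
            a, b = sorted((c, target))
            saddles.setdefault((a, b), flat[p])
            if persistence < min_depth:
                parent[c] = target

    # surviving components
    survivors = sorted({find(c) for c in range(len(comp_min_idx))},
                       key=lambda c: flat[comp_min_idx[c]])
    if energy_window is not None:
        survivors = [c for c in survivors
                     if flat[comp_min_idx[c]] <= energy_window]
    relabel = {c: i for i, c in enumerate(survivors)}
    basins = []
    comp_final = np.array([relabel.get(find(c), -1) if c >= 0 else -1 for c in comp])
    for c in survivors:
        i = relabel[c]
        members = np.nonzero(comp_final == i)[0]
        loc = np.unravel_index(comp_min_idx[c], shape)
        basins.append(Basin(label=i, location=loc,
                            f_min=float(flat[comp_min_idx[c]]), members=members))

    barriers = _minimax_saddles(fes, basins)
    return BasinSet(basins=basins, barriers=barriers, grid=fes)


def _minimax_saddles(fes: FESGrid, basins: list[Basin]) -> np.ndarray:
    """Pairwise minimax saddle heights via Kruskal-style union-find.

    Grid edges sorted by max endpoint energy are merged until basin minima
    join; the joining edge height is the minimax saddle.
    """
    n = len(basins)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, [b.f_min for b in basins])
    if n < 2:
        return out
    F = fes.F
    shape = F.shape
    flat = F.ravel()

    edges = []
    if F.ndim == 1:
        for i in range(len(flat) - 1):
            if np.isfinite(flat[i]) and np.isfinite(flat[i + 1]):
                edges.append((max(flat[i], flat[i + 1]), i, i + 1))
    else:
        nx, ny = shape
        for i in range(nx):
            for j in range(ny):
                p = i * ny + j
                if not np.isfinite(flat[p]):
                    continue
                if i + 1 < nx and np.isfinite(F[i + 1, j]):
                    edges.append((max(flat[p], F[i + 1, j]), p, p + ny))
                if j + 1 < ny and np.isfinite(F[i, j + 1]):
                    edges.append((max(flat[p], F[i, j + 1]), p, p + 1))
    edges.sort(key=lambda e: e[0])

    parent = np.arange(flat.size)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    mins = [np.ravel_multi_index(b.location, shape) for b in basins]
    remaining = {(i, j) for i in range(n) for j in range(i + 1, n)}
    for h, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
        done = []
        for (i, j) in remaining:
            if find(mins[i]) == find(mins[j]):
                out[i, j] = out[j, i] = h
                done.append((i, j))
        remaining -= set(done)
        if not remaining:
            break
    return out


def barrier_between(basin_set: BasinSet, label_a: int, label_b: int
                    ) -> tuple[float, float]:
    """Forward and reverse barrier heights between two basins.

    Returns (saddle - F_min_a, saddle - F_min_b); NaN with a warning when
    the sampled regions are disconnected.
    """
    saddle = basin_set.barriers[label_a, label_b]
    if np.isnan(saddle):
        import warnings
        warnings.warn("basins lie in disconnected sampled regions", stacklevel=2)
        return float("nan"), float("nan")
    fa = basin_set.basins[label_a].f_min
    fb = basin_set.basins[label_b].f_min
    return float(saddle - fa), float(saddle - fb)


@dataclass
class BindingResult:
    dg_bind: float             # kcal/mol, F_bound - F_unbound
    barrier: float             # kcal/mol, saddle relative to the unbound basin
    f_bound: float
    f_unbound: float


def _region_free_energy(fes: FESGrid, mask: np.ndarray, kT: float) -> float:
    """Basin free energy: -kT ln sum exp(-F/kT) over the region's points."""
    vals = fes.F[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("region contains no sampled grid points")
    ref = vals.min()
    return float(ref - kT * np.log(np.sum(np.exp(-(vals - ref) / kT))))


def binding_dg(fes: FESGrid, bound_mask: np.ndarray, unbound_mask: np.ndarray,
               temperature: float = 310.0) -> BindingResult:
    """Binding free energy between two disjoint grid regions.

    Each region's free energy is the log-sum-exp over its member points
    (catchment free energy, not the bare minimum); the barrier is the
    minimax saddle between the two regions' minima, measured from the
    unbound basin floor.
    """
    bound_mask = np.asarray(bound_mask, dtype=bool)
    unbound_mask = np.asarray(unbound_mask, dtype=bool)
    if bound_mask.shape != fes.F.shape or unbound_mask.shape != fes.F.shape:
        raise ValueError("region masks must match the grid shape")
    if np.any(bound_mask & unbound_mask):
        raise ValueError("bound and unbound regions must be disjoint")
    kT = kT_at(temperature)
    f_bound = _region_free_energy(fes, bound_mask, kT)
    f_unbound = _region_free_energy(fes, unbound_mask, kT)

    def region_min_basin(mask):
        masked = np.where(mask, fes.F, np.inf)
        return np.unravel_index(np.argmin(masked), fes.F.shape)

    basins = [Basin(0, region_min_basin(bound_mask),
                    float(fes.F[region_min_basin(bound_mask)]), np.zeros(0, int)),
              Basin(1, region_min_basin(unbound_mask),
                    float(fes.F[region_min_basin(unbound_mask)]), np.zeros(0, int))]
    saddle = _minimax_saddles(fes, basins)[0, 1]
    barrier = float(saddle - basins[1].f_min) if np.isfinite(saddle) else float("nan")
    return BindingResult(dg_bind=f_bound - f_unbound, barrier=barrier,
                         f_bound=f_bound, f_unbound=f_unbound)
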