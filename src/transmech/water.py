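"""Water-wire permeability, permeable-state lifetimes, membrane water flux
and trapped-water counts.

A frame is *permeable* when a chain of water oxygens, consecutive pairs
within a cutoff (4.0 A), connects the extracellular and intracellular bulk
through the membrane region. Flux is counted per water molecule by a
finite-state machine over the ordered crossings of three planes — inner
leaflet, bilayer midplane, outer leaflet: crossing all three bottom-to-top
is one efflux, top-to-bottom one influx, and out-of-order crossings reset
progress to the most recent consistent prefix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, MembraneGeometry, Trajectory
from .synthetic import PermeationEvent

__all__ = [
    "PermeabilityRecord", "LifetimeStats", "CavityRegion",
    "detect_water_wire", "permeability_series",
    "count_flux_events", "count_trapped_waters",
]

DEFAULT_CUTOFF = 4.0  # A, O-O connectivity


@dataclass
class PermeabilityRecord:
    frame_index: int
    permeable: bool
    wire_size: int           # waters on one shortest connecting path; 0 if none


@dataclass
class LifetimeStats:
    """Statistics of maximal runs of consecutive permeable frames (ns)."""

    mean: float
    sd: float
    median: float
    max: float
    n_episodes: int


def _wire_graph(coords: np.ndarray, membrane: MembraneGeometry, cutoff: float,
                channel_axis_xy: Optional[np.ndarray] = None,
                channel_radius: Optional[float] = None):
    """Internal nodes (between the leaflet planes) and their bulk contacts.

    Returns (internal indices, edges among internal nodes, flags of contact
    with the extracellular / intracellular bulk). Bulk waters are collapsed
    into two super-nodes: any internal water within the cutoff of a water
    beyond a leaflet plane is connected to that side's terminal.
    """
    z = coords[:, 2]
    inner, outer = membrane.inner_leaflet_z, membrane.outer_leaflet_z
    internal = np.nonzero((z >= inner) & (z <= outer))[0]
    if channel_axis_xy is not None and channel_radius is not None:
        r2 = ((coords[internal, :2] - channel_axis_xy) ** 2).sum(axis=1)
        internal = internal[r2 <= channel_radius ** 2]
    above = np.nonzero(z > outer)[0]
    below = np.nonzero(z < inner)[0]

    if internal.size == 0:
        return internal, np.zeros((0, 2), int), np.zeros(0, bool), np.zeros(0, bool)

    tree_int = cKDTree(coords[internal])
    pairs = tree_int.query_pairs(r=cutoff, output_type="ndarray")

    def bulk_contact(bulk_idx):
        if bulk_idx.size == 0:
            return np.zeros(internal.size, dtype=bool)
        tree_bulk = cKDTree(coords[bulk_idx])
        hits = tree_int.query_ball_tree(tree_bulk, r=cutoff)
        return np.array([len(h) > 0 for h in hits])

    return internal, pairs, bulk_contact(above), bulk_contact(below)


def detect_water_wire(frame: Frame, waters: np.ndarray,
                      membrane: MembraneGeometry,
                      cutoff: float = DEFAULT_CUTOFF,
                      channel_axis_xy: Optional[np.ndarray] = None,
                      channel_radius: Optional[float] = None,
                      frame_index: int = 0) -> PermeabilityRecord:
    """Is there a water wire connecting the two bulk reservoirs?

    Wire size is the number of waters on one shortest terminal-to-terminal
    path (breadth-first over the O-O graph). An optional cylindrical mask
    (axis position in XY plus radius) restricts wire nodes to the channel.
    """
    waters = np.asarray(waters, dtype=int)
    coords = frame.coords[waters]
    internal, pairs, ext, intra = _wire_graph(
        coords, membrane, cutoff, channel_axis_xy, channel_radius)
    n = internal.size
    if n == 0 or not ext.any() or not intra.any():
        return PermeabilityRecord(frame_index, False, 0)

    # BFS from the extracellular terminal over internal nodes
    adj = [[] for _ in range(n)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    dist = np.full(n, -1)
    frontier = np.nonzero(ext)[0].tolist()
    for s in frontier:
        dist[s] = 1  # path length counted in water nodes
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    reached = (dist > 0) & intra
    if not reached.any():
        return PermeabilityRecord(frame_index, False, 0)
    return PermeabilityRecord(frame_index, True, int(dist[reached].min()))


def permeability_series(traj: Trajectory, waters: np.ndarray,
                        membrane: MembraneGeometry,
                        cutoff: float = DEFAULT_CUTOFF, **wire_kwargs
                        ) -> tuple[list[PermeabilityRecord], LifetimeStats, float]:
    """Per-frame permeability, episode lifetime statistics and the
    permeable fraction of the trajectory."""
    records = [detect_water_wire(f, waters, membrane, cutoff,
                                 frame_index=i, **wire_kwargs)
               for i, f in enumerate(traj)]
    flags = np.array([r.permeable for r in records])
    fraction = float(flags.mean())
    runs = run_lengths(flags)
    lifetimes = runs * traj.frame_interval
    if len(lifetimes):
        stats = LifetimeStats(
            mean=float(lifetimes.mean()),
            sd=float(lifetimes.std(ddof=1)) if len(lifetimes) > 1 else 0.0,
            median=float(np.median(lifetimes)),
            max=float(lifetimes.max()),
            n_episodes=len(lifetimes))
    else:
        stats = LifetimeStats(0.0, 0.0, 0.0, 0.0, 0)
    return records, stats, fraction


def run_lengths(flags: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a boolean series."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return np.zeros(0, dtype=int)
    padded = np.concatenate([[False], flags, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return ends - starts


def count_flux_events(traj: Trajectory, waters: np.ndarray,
                      membrane: MembraneGeometry,
                      strict: bool = True) -> list[PermeationEvent]:
    """Complete three-plane crossings per water, as permeation events.

    A water leaving the intracellular bulk (below the inner leaflet) that
    reaches the extracellular bulk (above the outer leaflet) without
    returning completes one efflux; the reverse is one influx. Dips back
    toward — but not into — the origin bulk keep the first-plane crossing
    (`most recent consistent prefix`); re-entering the origin bulk resets
    progress entirely. ``strict=False`` additionally resets on any mid-plane
    back-crossing. Crossing times are stamped at the first frame observed on
    the far side of a plane.

    Waters jumping more than half the box height in one frame are excluded
    with a warning (broken/teleporting trajectories).
    """
    waters = np.asarray(waters, dtype=int)
    z = np.stack([f.coords[waters, 2] for f in traj])      # (n_frames, n_waters)
    times = traj.times
    inner, mid, outer = membrane.planes
    half_box = 0.5 * float(traj[0].box[2])
    events: list[PermeationEvent] = []

    spacing = min(mid - inner, outer - mid)
    if np.any(np.abs(np.diff(z, axis=0)) >= spacing):
        warnings.warn("some waters move further than the plane spacing in "
                      "one frame; crossings may be under-resolved", stacklevel=2)

    for w in range(z.shape[1]):
        zw = z[:, w]
        if np.any(np.abs(np.diff(zw)) > half_box):
            warnings.warn(f"water {w} teleports (> half box per frame); excluded",
                          stacklevel=2)
            continue
        # region code per frame: 0 below inner, 1 inner-mid, 2 mid-outer, 3 above outer
        region = np.digitize(zw, [inner, mid, outer])
        origin = region[0] if region[0] in (0, 3) else -1
        t_first = times[0]
        armed = False  # holds a valid first-plane crossing
        changes = np.nonzero(np.diff(region) != 0)[0] + 1
        for i in changes:
            r_prev, r = int(region[i - 1]), int(region[i])
            if origin == 0:
                if r_prev == 0 and r >= 1:
                    armed = True             # crossed the inner plane upward
                    t_first = times[i]
                elif r == 0:
                    armed = False            # fell back into the origin bulk
                elif not strict and r < r_prev:
                    armed = False            # lenient mode: any back-crossing resets
                if r == 3:
                    if armed:
                        events.append(PermeationEvent(
                            water_id=int(waters[w]), direction="efflux",
                            t_start=float(t_first), t_end=float(times[i])))
                    origin = 3
                    armed = False
            elif origin == 3:
                if r_prev == 3 and r <= 2:
                    armed = True             # crossed the outer plane downward
                    t_first = times[i]
                elif r == 3:
                    armed = False
                elif not strict and r > r_prev:
                    armed = False
                if r == 0:
                    if armed:
                        events.append(PermeationEvent(
                            water_id=int(waters[w]), direction="influx",
                            t_start=float(t_first), t_end=float(times[i])))
                    origin = 0
                    armed = False
            else:
                # started inside the membrane: wait for the first bulk visit
                if r in (0, 3):
                    origin = r
    events.sort(key=lambda ev: (ev.t_end, ev.water_id))
    return events


@dataclass
class CavityRegion:
    """Sphere or axis-aligned box defining the ion-binding cavity."""

    kind: str                           # "sphere" | "box"
    center: Optional[np.ndarray] = None  # sphere
    radius: float = 0.0
    lower: Optional[np.ndarray] = None  # box corners
    upper: Optional[np.ndarray] = None

    def contains(self, coords: np.ndarray) -> np.ndarray:
        if self.kind == "sphere":
            if self.center is None or self.radius <= 0:
                raise ValueError("sphere region needs center and positive radius")
            return ((coords - np.asarray(self.center)) ** 2).sum(axis=1) <= self.radius ** 2
        if self.kind == "box":
            if self.lower is None or self.upper is None:
                raise ValueError("box region needs lower and upper corners")
            lo, hi = np.asarray(self.lower), np.asarray(self.upper)
            return np.all((coords >= lo) & (coords <= hi), axis=1)
        raise ValueError(f"unknown region kind {self.kind!r}")


def count_trapped_waters(frame: Frame, waters: np.ndarray,
                         cavity: CavityRegion, membrane: MembraneGeometry,
                         cutoff: float = DEFAULT_CUTOFF) -> int:
    """Waters inside the cavity not connected to either bulk reservoir.

    Connectivity uses the same O-O distance graph as the wire detector: a
    cavity water connected (through any chain of between-leaflet waters) to
    a bulk-contacting water is exchangeable, not trapped.
    """
    waters = np.asarray(waters, dtype=int)
    coords = frame.coords[waters]
    in_cavity_all = cavity.contains(coords)
    internal, pairs, ext, intra = _wire_graph(coords, membrane, cutoff)
    in_cavity_internal = in_cavity_all[internal]
    # cavity waters outside the membrane slab are by definition bulk-exposed
    n_cavity_outside = int(in_cavity_all.sum() - in_cavity_internal.sum())

    n = internal.size
    if n == 0:
        return 0
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots = np.array([find(i) for i in range(n)])
    bulk_roots = set(roots[ext | intra].tolist())
    trapped = [i for i in range(n)
               if in_cavity_internal[i] and roots[i] not in bulk_roots]
    del n_cavity_outside  # exposed by construction; not counted as trapped
    return len(trapped)
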