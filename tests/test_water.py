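"""Water-wire percolation, permeable-lifetime statistics, flux counting and
trapped-water counts, each against an independent oracle."""

import numpy as np
import pytest

from transmech import synthetic as syn
from transmech import water as wat
from transmech.core import Frame, MembraneGeometry, Trajectory

MEM = MembraneGeometry(-15.0, 15.0)


def _chain(z_lo=-17.0, z_hi=19.0, spacing=3.9):
    z = np.arange(z_lo, z_hi, spacing)
    coords = np.zeros((len(z), 3))
    coords[:, 2] = z
    return coords


def test_wire_single_file_chain_permeable():
    coords = _chain()
    rec = wat.detect_water_wire(Frame(0, coords), np.arange(len(coords)), MEM)
    assert rec.permeable
    n_internal = int(((coords[:, 2] >= -15) & (coords[:, 2] <= 15)).sum())
    assert rec.wire_size == n_internal
    assert rec.wire_size >= 2


def test_wire_broken_by_small_gap():
    coords = _chain()
    coords[5:, 2] += 0.3  # one O-O gap becomes 4.2 A
    rec = wat.detect_water_wire(Frame(0, coords), np.arange(len(coords)), MEM)
    assert not rec.permeable and rec.wire_size == 0


def test_wire_no_waters():
    rec = wat.detect_water_wire(Frame(0, np.zeros((0, 3))), np.arange(0), MEM)
    assert not rec.permeable and rec.wire_size == 0


def _bfs_oracle(coords, membrane, cutoff):
    """Brute-force O(n^2) distance graph + BFS between the two reservoirs."""
    z = coords[:, 2]
    inner, outer = membrane.inner_leaflet_z, membrane.outer_leaflet_z
    nodes = np.nonzero((z >= inner) & (z <= outer))[0]
    above = np.nonzero(z > outer)[0]
    below = np.nonzero(z < inner)[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    start = {i for i in nodes if len(above) and d[i, above].min() <= cutoff}
    goal = {i for i in nodes if len(below) and d[i, below].min() <= cutoff}
    frontier, seen = set(start), set(start)
    while frontier:
        if frontier & goal:
            return True
        nxt = set()
        for u in frontier:
            for v in nodes:
                if v not in seen and d[u, v] <= cutoff:
                    nxt.add(v)
                    seen.add(v)
        frontier = nxt
    return bool(seen & goal)


def test_wire_agrees_with_bfs_oracle_and_cutoff_monotone(rng):
    n_perm = 0
    for trial in range(60):
        coords = rng.uniform([-12, -12, -20], [12, 12, 20], size=(120, 3))
        frame = Frame(0, coords)
        rec = wat.detect_water_wire(frame, np.arange(120), MEM, cutoff=5.5)
        assert rec.permeable == _bfs_oracle(coords, MEM, 5.5)
        n_perm += rec.permeable
        if rec.permeable:  # larger cutoff can never break a wire
            assert wat.detect_water_wire(frame, np.arange(120), MEM,
                                         cutoff=7.0).permeable
    assert 0 < n_perm < 60  # both verdicts exercised


def test_wire_symmetric_under_terminal_swap(rng):
    """Flipping the slab in z swaps the bulk terminals; the verdict holds."""
    for trial in range(20):
        coords = rng.uniform([-12, -12, -20], [12, 12, 20], size=(120, 3))
        rec = wat.detect_water_wire(Frame(0, coords), np.arange(120), MEM, 5.5)
        flipped = coords.copy()
        flipped[:, 2] *= -1
        rec_f = wat.detect_water_wire(Frame(0, flipped), np.arange(120), MEM, 5.5)
        assert rec.permeable == rec_f.permeable


def _series_from_flags(flags):
    """Build a trajectory whose frames are permeable iff flags[i]."""
    chain = _chain()
    broken = chain.copy()
    broken[5:, 2] += 1.0
    frames = [Frame(i * 0.1, chain if f else broken)
              for i, f in enumerate(flags)]
    return Trajectory(frames, 0.1)


def test_permeability_series_all_and_alternating():
    traj = _series_from_flags([True] * 6)
    _, stats, frac = wat.permeability_series(traj, np.arange(10), MEM)
    assert frac == 1.0 and stats.n_episodes == 1
    assert stats.max == pytest.approx(0.6)
    traj2 = _series_from_flags([True, False] * 5)
    _, stats2, frac2 = wat.permeability_series(traj2, np.arange(10), MEM)
    assert frac2 == 0.5 and stats2.n_episodes == 5
    assert stats2.mean == pytest.approx(0.1)
    assert stats2.sd == pytest.approx(0.0)


def test_run_lengths_match_rle_oracle(rng):
    flags = rng.random(200) < 0.4
    runs = wat.run_lengths(flags)
    # independent run-length encoding
    oracle = []
    count = 0
    for f in flags:
        if f:
            count += 1
        elif count:
            oracle.append(count)
            count = 0
    if count:
        oracle.append(count)
    assert runs.tolist() == oracle


def _traj_from_z(z_series, frame_interval=0.1):
    """One-water trajectory from a z series."""
    z = np.asarray(z_series, dtype=float)
    frames = [Frame(i * frame_interval, np.array([[0.0, 0.0, zz]]),
                    box=np.array([40.0, 40.0, 200.0]))
              for i, zz in enumerate(z)]
    return Trajectory(frames, frame_interval)


def test_flux_monotone_efflux():
    z = np.linspace(-19.9, 20.1, 41)  # unit steps, never exactly on a plane
    events = wat.count_flux_events(_traj_from_z(z), np.array([0]), MEM)
    assert len(events) == 1
    e = events[0]
    assert e.direction == "efflux"
    # first frame past each terminal plane: z > -15 at frame 5, z > 15 at frame 35
    assert e.t_start == pytest.approx(0.5)
    assert e.t_end == pytest.approx(3.5)


def test_flux_partial_path_no_event():
    z = np.concatenate([np.linspace(-20, -5, 16), np.linspace(-5, -20, 16)])
    frames = [Frame(i * 0.1, np.array([[0.0, 0.0, zz]]),
                    box=np.array([40.0, 40.0, 200.0]))
              for i, zz in enumerate(z)]
    # drop duplicate time at the joint
    traj = Trajectory([Frame(i * 0.1, f.coords, f.box)
                       for i, f in enumerate(frames)], 0.1)
    assert wat.count_flux_events(traj, np.array([0]), MEM) == []


def test_flux_dip_keeps_prefix_strict_resets_lenient():
    # crosses inner, mid, dips back below mid, re-crosses, completes
    z = np.array([-20, -10, 2, -2, -2, 3, 8, 20], dtype=float)
    traj = _traj_from_z(z)
    strict = wat.count_flux_events(traj, np.array([0]), MEM, strict=True)
    assert len(strict) == 1
    assert strict[0].t_start == pytest.approx(0.1)  # original inner crossing
    lenient = wat.count_flux_events(traj, np.array([0]), MEM, strict=False)
    assert lenient == []  # back-crossing voids the sequence entirely


def test_flux_return_to_origin_resets():
    z = np.array([-20, -10, 5, -10, -20, -10, 5, 20], dtype=float)
    events = wat.count_flux_events(_traj_from_z(z), np.array([0]), MEM)
    assert len(events) == 1
    assert events[0].t_start == pytest.approx(0.5)  # crossing after the reset


def _replay_oracle(z, times, planes):
    """Independent frame-by-frame replay of the ordered-crossing rule."""
    inner, mid, outer = planes
    events = []
    origin = None
    if z[0] < inner:
        origin = "below"
    elif z[0] > outer:
        origin = "above"
    armed = False
    t_first = None
    for i in range(1, len(z)):
        if origin == "below":
            if z[i - 1] < inner and z[i] >= inner:
                armed, t_first = True, times[i]
            if z[i] < inner:
                armed = False
            if z[i] > outer:
                if armed:
                    events.append(("efflux", t_first, times[i]))
                origin, armed = "above", False
        elif origin == "above":
            if z[i - 1] > outer and z[i] <= outer:
                armed, t_first = True, times[i]
            if z[i] > outer:
                armed = False
            if z[i] < inner:
                if armed:
                    events.append(("influx", t_first, times[i]))
                origin, armed = "below", False
        else:
            if z[i] < inner:
                origin = "below"
            elif z[i] > outer:
                origin = "above"
    return events


def test_flux_random_walks_match_replay_oracle(rng):
    n_waters, n_frames = 80, 600
    z = np.empty((n_frames, n_waters))
    z[0] = rng.uniform(-25, 25, n_waters)
    for i in range(1, n_frames):
        z[i] = np.clip(z[i - 1] + rng.normal(0, 4.0, n_waters), -30, 30)
    frames = [Frame(i * 0.1, np.column_stack(
        [np.zeros(n_waters), np.zeros(n_waters), z[i]]),
        box=np.array([40.0, 40.0, 200.0])) for i in range(n_frames)]
    traj = Trajectory(frames, 0.1)
    events = wat.count_flux_events(traj, np.arange(n_waters), MEM)
    oracle = []
    for w in range(n_waters):
        for direction, t0, t1 in _replay_oracle(z[:, w], traj.times, MEM.planes):
            oracle.append((w, direction, round(t0, 6), round(t1, 6)))
    got = sorted((e.water_id, e.direction, round(e.t_start, 6), round(e.t_end, 6))
                 for e in events)
    assert got == sorted(oracle)
    assert len(events) > 10  # the walk regime actually produces crossings


def test_flux_time_reversal_swaps_directions(rng):
    n_waters, n_frames = 40, 400
    z = np.empty((n_frames, n_waters))
    z[0] = rng.uniform(-25, 25, n_waters)
    for i in range(1, n_frames):
        z[i] = np.clip(z[i - 1] + rng.normal(0, 4.0, n_waters), -30, 30)

    def traj_of(zz):
        return Trajectory([Frame(i * 0.1, np.column_stack(
            [np.zeros(n_waters), np.zeros(n_waters), zz[i]]),
            box=np.array([40.0, 40.0, 200.0])) for i in range(n_frames)], 0.1)

    fwd = wat.count_flux_events(traj_of(z), np.arange(n_waters), MEM)
    rev = wat.count_flux_events(traj_of(z[::-1]), np.arange(n_waters), MEM)
    swap = {"efflux": "influx", "influx": "efflux"}
    total_t = (n_frames - 1) * 0.1
    fwd_mapped = sorted((e.water_id, swap[e.direction],
                         round(total_t - e.t_end, 6)) for e in fwd)
    rev_keys = sorted((e.water_id, e.direction, round(e.t_start, 6)) for e in rev)
    assert len(fwd) == len(rev) > 0
    # endpoints map within one frame interval (one-sided crossing stamp)
    for (w1, d1, t1), (w2, d2, t2) in zip(fwd_mapped, rev_keys):
        assert (w1, d1) == (w2, d2)
        assert abs(t1 - t2) <= 0.1 + 1e-9


def test_flux_on_generator_output_matches_ground_truth():
    events = [syn.ScriptedEvent(2, "efflux", 20, 90),
              syn.ScriptedEvent(5, "influx", 120, 260),
              syn.ScriptedEvent(9, "efflux", 200, 300)]
    spec = syn.WaterSlabSpec(n_waters=60, scripted_events=events, seed=6)
    traj, atoms, truth = syn.make_water_slab(spec, 400)
    found = wat.count_flux_events(traj, np.arange(len(atoms)), spec.membrane)
    key = lambda e: (e.water_id, e.direction, round(e.t_start, 9), round(e.t_end, 9))
    assert sorted(map(key, found)) == sorted(map(key, truth))


def test_teleporting_water_excluded():
    z = np.array([-20.0, 150.0, -20.0, 5.0, 20.0])
    frames = [Frame(i * 0.1, np.array([[0.0, 0.0, zz]]),
                    box=np.array([40.0, 40.0, 200.0]))
              for i, zz in enumerate(z)]
    with pytest.warns(UserWarning, match="teleports"):
        events = wat.count_flux_events(Trajectory(frames, 0.1),
                                       np.array([0]), MEM)
    assert events == []


# -- trapped waters -----------------------------------------------------------

def test_trapped_waters_sealed_pocket():
    # 3 waters isolated mid-membrane + a bulk-connected chain elsewhere
    pocket = np.array([[0.0, 0, -2], [0.0, 2, 0], [0.0, 0, 2]])
    chain = _chain()
    chain[:, 0] += 25.0
    coords = np.vstack([pocket, chain])
    cavity = wat.CavityRegion(kind="sphere", center=np.array([0.0, 0.7, 0.0]),
                              radius=5.0)
    n = wat.count_trapped_waters(Frame(0, coords), np.arange(len(coords)),
                                 cavity, MEM)
    assert n == 3


def test_trapped_waters_zero_when_connected_to_bulk():
    chain = _chain()  # spans both bulks, spacing 3.9
    cavity = wat.CavityRegion(kind="sphere", center=np.zeros(3), radius=6.0)
    n = wat.count_trapped_waters(Frame(0, chain), np.arange(len(chain)),
                                 cavity, MEM)
    assert n == 0


def test_trapped_waters_match_connectivity_oracle(rng):
    cavity = wat.CavityRegion(kind="box", lower=np.array([-6.0, -6, -6]),
                              upper=np.array([6.0, 6, 6]))
    for trial in range(25):
        coords = rng.uniform([-15, -15, -22], [15, 15, 22], size=(50, 3))
        n = wat.count_trapped_waters(Frame(0, coords), np.arange(50), cavity,
                                     MEM, cutoff=4.5)
        # oracle: BFS from each cavity water; trapped iff no bulk reachable
        z = coords[:, 2]
        inside = (z >= MEM.inner_leaflet_z) & (z <= MEM.outer_leaflet_z)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        trapped = 0
        for i in np.nonzero(cavity.contains(coords) & inside)[0]:
            frontier, seen = {i}, {i}
            reach_bulk = False
            while frontier and not reach_bulk:
                nxt = set()
                for u in frontier:
                    for v in range(50):
                        if v in seen or d[u, v] > 4.5:
                            continue
                        if not inside[v]:
                            reach_bulk = True
                        else:
                            nxt.add(v)
                            seen.add(v)
                frontier = nxt
            trapped += not reach_bulk
        assert n == trapped


def test_cavity_region_validation():
    with pytest.raises(ValueError):
        wat.CavityRegion(kind="sphere").contains(np.zeros((1, 3)))
    with pytest.raises(ValueError):
        wat.CavityRegion(kind="pyramid").contains(np.zeros((1, 3)))
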