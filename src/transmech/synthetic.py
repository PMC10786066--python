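"""Synthetic data with planted ground truth.

Everything the analysis pipeline consumes can be generated here with exactly
known answers: two-state 12-helix bundles whose mobile pair differs by a
planted rigid rotation (the rocking-bundle motion) and whose kinked helix
differs by a planted intrahelical angle; water slabs with diffusing oxygens
and scripted permeation paths; two-state Gaussian ensembles of interhelical
distances with planted discriminative pairs; and overdamped Langevin
trajectories on analytic potentials.

The generators exist so that parameter-recovery tests can assert exact or
statistically bounded agreement between what was planted and what the
analysis modules measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import _integrators
from .core import (AtomTable, Frame, HelixSegment, LabeledEnsemble,
                   MembraneGeometry, StateLabel, TMTopology, Trajectory,
                   center_of_mass, select_backbone)

__all__ = [
    "BundleSpec", "WaterSlabSpec", "FeatureEnsembleSpec", "PotentialSpec",
    "ScriptedEvent", "GenerationError",
    "make_two_state_bundle", "make_transition_trajectory",
    "make_water_slab", "make_feature_ensemble", "langevin_trajectory",
]


class GenerationError(RuntimeError):
    """A generator spec was internally infeasible."""


# ---------------------------------------------------------------------------
# Helix bundles
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """Two-state 12-helix bundle with a planted rocking-bundle rotation.

    The mobile pair (TM4/TM9 analogues) is rigidly rotated by
    ``mobile_rotation_deg`` between states about an axis through the
    intracellular anchor of the bundle; the kinked helix (TM10 analogue)
    changes its intrahelical angle between ``kink_deg_state_a`` and
    ``kink_deg_state_b``. Defaults plant the motions reported for NKCC1-like
    transporters: a 14 deg bundle rotation and a 151.2 -> 169.2 deg
    helix straightening.
    """

    n_helices: int = 12
    helix_length: int = 28            # residues
    rise_per_residue: float = 1.5     # A
    ring_radius: float = 18.0         # A, helix placement circle
    mobile_rotation_deg: float = 14.0
    kink_deg_state_a: float = 151.2
    kink_deg_state_b: float = 169.2
    noise_sigma: float = 0.0          # A, per-coordinate Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mobile_rotation_deg <= 90.0):
            raise ValueError("mobile_rotation_deg must be in [0, 90]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_helices < 4:
            raise ValueError("need at least 4 helices (mobile pair + anchors)")


MOBILE_IDS = ("TM4", "TM9")
STATIC_IDS = ("TM1", "TM2", "TM6", "TM7")
ANCHOR_IDS = ("TM2", "TM7")
KINKED_ID = "TM10"
TIP_RESIDUES = 4  # terminal residues per helix end forming a "tip"

# Placement around the bundle circle: the mobile pair sits adjacent on one
# side with the static scaffold across from it (as in the inverted-repeat
# fold), so the angle reference arm B->C spans the bundle instead of
# degenerating to a short vector.
RING_ORDER = ("TM2", "TM7", "TM1", "TM3", "TM8", "TM10",
              "TM4", "TM9", "TM5", "TM11", "TM12", "TM6")


def _helix_trace(spec: BundleSpec, base: np.ndarray, kink_deg: Optional[float],
                 bend_dir: Optional[np.ndarray] = None) -> np.ndarray:
    """Ideal Calpha trace rising along +Z from ``base``; optional single kink.

    A kinked helix runs straight to its middle residue (the vertex) and then
    continues along a direction tilted so the intrahelical angle — measured
    at the vertex between the two arms — equals ``kink_deg`` (180 = straight).
    ``bend_dir`` is the in-plane unit vector the upper arm tilts toward
    (radially outward by default, so the arm swings away from the bundle).
    """
    n = spec.helix_length
    rise = spec.rise_per_residue
    pts = np.zeros((n, 3))
    if kink_deg is None:
        pts[:, 2] = np.arange(n) * rise
    else:
        m = n // 2  # vertex residue (0-based)
        bend = np.radians(180.0 - kink_deg)
        bd = np.array([1.0, 0.0, 0.0]) if bend_dir is None else bend_dir
        d2 = np.sin(bend) * bd + np.cos(bend) * np.array([0.0, 0.0, 1.0])
        pts[: m + 1, 2] = np.arange(m + 1) * rise
        for j in range(m + 1, n):
            pts[j] = pts[m] + (j - m) * rise * d2
    return pts + base


# Per-residue backbone pseudo-atom offsets chosen so each residue's backbone
# center of mass coincides exactly with its trace point (N/C and CA/O are
# placed antisymmetrically), keeping the COM-based angle metrics exact.
_OFF_P = np.array([0.6, 0.0, 0.0])
_OFF_Q = np.array([0.0, 0.6, 0.0])
_BB_OFFSETS = {"N": _OFF_P, "C": -_OFF_P, "O": _OFF_Q, "CA": -_OFF_Q}
_BB_ORDER = ("N", "CA", "C", "O")


def build_topology(spec: BundleSpec) -> TMTopology:
    """Atom table + helix annotations for the bundle (state-independent)."""
    names, resids, resnames = [], [], []
    helices = []
    for h in range(spec.n_helices):
        hid = f"TM{h + 1}"
        r0 = 100 * (h + 1) + 1
        r1 = r0 + spec.helix_length - 1
        bend = None
        if hid == KINKED_ID and spec.n_helices >= 10:
            vertex = r0 + spec.helix_length // 2
            bend = (vertex, vertex)
        helices.append(HelixSegment(
            helix_id=hid,
            residue_range=(r0, r1),
            intracellular_tip=(r0, r0 + TIP_RESIDUES - 1),
            extracellular_tip=(r1 - TIP_RESIDUES + 1, r1),
            bend_window=bend,
        ))
        for res in range(r0, r1 + 1):
            for an in _BB_ORDER:
                names.append(an)
                resids.append(res)
                resnames.append("ALA")
    atoms = AtomTable.from_columns(names, resids, resnames)
    n_h = spec.n_helices
    return TMTopology(
        atoms=atoms,
        helices=helices,
        static_domain=[h for h in STATIC_IDS if int(h[2:]) <= n_h],
        mobile_bundle=[h for h in MOBILE_IDS if int(h[2:]) <= n_h],
        static_anchor=[h for h in ANCHOR_IDS if int(h[2:]) <= n_h],
    )


def _base_coords(spec: BundleSpec, topo: TMTopology, kink_deg: float) -> np.ndarray:
    """Unrotated (state A frame of reference) coordinates for all atoms."""
    coords = np.zeros((len(topo.atoms), 3))
    i = 0
    z0 = -0.5 * (spec.helix_length - 1) * spec.rise_per_residue
    slot_of = {hid: k for k, hid in enumerate(RING_ORDER)}
    for h, helix in enumerate(topo.helices):
        slot = slot_of.get(helix.helix_id, h)
        angle = 2 * np.pi * slot / spec.n_helices
        base = np.array([spec.ring_radius * np.cos(angle),
                         spec.ring_radius * np.sin(angle), z0])
        kd = kink_deg if helix.bend_window is not None else None
        radial = np.array([np.cos(angle), np.sin(angle), 0.0])
        trace = _helix_trace(spec, base, kd, bend_dir=radial)
        for j in range(spec.helix_length):
            for an in _BB_ORDER:
                coords[i] = trace[j] + _BB_OFFSETS[an]
                i += 1
    return coords


def _anchor_points(spec: BundleSpec, topo: TMTopology, coords: np.ndarray):
    """Tip centers of mass defining the rocking rotation (state A geometry)."""
    frame = Frame(0.0, coords)

    def tip_com(helix_ids, which):
        sels = []
        for hid in helix_ids:
            h = topo.helix(hid)
            win = h.extracellular_tip if which == "ec" else h.intracellular_tip
            sels.append(select_backbone(topo, hid, win))
        return center_of_mass(frame, np.concatenate(sels))

    a = tip_com(topo.mobile_bundle, "ec")     # mobile extracellular tips
    b = tip_com(topo.mobile_bundle, "ic")     # mobile intracellular tips (vertex)
    c = tip_com(topo.static_anchor, "ic")     # static intracellular anchor
    return a, b, c


def _mobile_atom_indices(topo: TMTopology) -> np.ndarray:
    sels = [topo.atoms.select(residues=topo.helix(hid).residues())
            for hid in topo.mobile_bundle]
    return np.concatenate(sels)


def _build_state_coords(spec: BundleSpec, topo: TMTopology,
                        rotation_deg: float, kink_deg: float) -> np.ndarray:
    """Coordinates with the mobile bundle rotated by ``rotation_deg``.

    The rotation axis passes through the mobile bundle's intracellular tip
    COM (which is therefore exactly invariant) and is perpendicular to the
    plane spanned by the bundle axis and the static anchor direction, so the
    measured bundle angle changes by exactly ``rotation_deg``.
    """
    coords = _base_coords(spec, topo, kink_deg)
    if rotation_deg == 0.0:
        return coords
    a, b, c = _anchor_points(spec, topo, _base_coords(spec, topo, spec.kink_deg_state_a))
    u = a - b
    v = c - b
    axis = np.cross(u, v)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        raise GenerationError("degenerate anchor geometry: bundle axis parallel to anchor")
    axis /= nrm
    # rotating by -angle about u x v moves the bundle axis away from the
    # anchor direction, increasing the bundle angle by exactly the rotation
    rot = Rotation.from_rotvec(-np.radians(rotation_deg) * axis)
    mob = _mobile_atom_indices(topo)
    coords[mob] = rot.apply(coords[mob] - b) + b
    _check_collisions(spec, topo, coords)
    return coords


def _check_collisions(spec: BundleSpec, topo: TMTopology, coords: np.ndarray) -> None:
    """Reject geometries where distinct helices come closer than 2 A."""
    helix_of = np.full(len(topo.atoms), -1)
    for k, h in enumerate(topo.helices):
        helix_of[topo.atoms.select(residues=h.residues())] = k
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2.0, output_type="ndarray")
    if pairs.size and np.any(helix_of[pairs[:, 0]] != helix_of[pairs[:, 1]]):
        raise GenerationError("planted rotation brings helices closer than 2 A")


def make_two_state_bundle(spec: BundleSpec, n_frames_per_state: int = 100
                          ) -> tuple[TMTopology, LabeledEnsemble]:
    """Generate the two-state ensemble: state A labelled IO, state B OO.

    State B's mobile-bundle axis is rotated by exactly
    ``spec.mobile_rotation_deg`` (before noise) relative to state A, and the
    kinked helix angle goes from ``kink_deg_state_a`` to ``kink_deg_state_b``.
    Static helices are identical across states up to noise.
    """
    topo = build_topology(spec)
    coords_a = _build_state_coords(spec, topo, 0.0, spec.kink_deg_state_a)
    coords_b = _build_state_coords(spec, topo, spec.mobile_rotation_deg,
                                   spec.kink_deg_state_b)
    rng = np.random.default_rng(spec.seed)
    frames, labels = [], []
    t = 0
    for coords, label in ((coords_a, StateLabel.IO), (coords_b, StateLabel.OO)):
        for _ in range(n_frames_per_state):
            noisy = coords + rng.normal(0.0, spec.noise_sigma, coords.shape) \
                if spec.noise_sigma > 0 else coords.copy()
            frames.append(Frame(time=float(t), coords=noisy))
            labels.append(label)
            t += 1
    return topo, LabeledEnsemble(frames, labels)


def make_transition_trajectory(spec: BundleSpec, n_frames: int,
                               frame_interval: float = 1.0) -> tuple[TMTopology, Trajectory]:
    """Trajectory interpolating state A -> state B monotonically.

    Frame k carries a mobile rotation of ``k/(n-1) * mobile_rotation_deg``
    and a linearly interpolated kink angle, plus per-frame noise.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    topo = build_topology(spec)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for k in range(n_frames):
        f = k / (n_frames - 1)
        coords = _build_state_coords(
            spec, topo, f * spec.mobile_rotation_deg,
            (1 - f) * spec.kink_deg_state_a + f * spec.kink_deg_state_b)
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        frames.append(Frame(time=k * frame_interval, coords=coords))
    return topo, Trajectory(frames, frame_interval)


# ---------------------------------------------------------------------------
# Water slab with scripted permeation
# ---------------------------------------------------------------------------

@dataclass
class ScriptedEvent:
    """One planted complete permeation: water ``water_id`` crosses all three
    membrane planes in order within frames [start_frame, end_frame]."""

    water_id: int
    direction: str                    # "efflux" (inward->outward) or "influx"
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.direction not in ("efflux", "influx"):
            raise ValueError("direction must be 'efflux' or 'influx'")
        if self.end_frame <= self.start_frame + 3:
            raise ValueError("event window too short to cross three planes")


@dataclass
class PermeationEvent:
    """A completed three-plane crossing found in (or planted into) a trajectory."""

    water_id: int
    direction: str
    t_start: float                    # ns, first-plane crossing
    t_end: float                      # ns, third-plane crossing

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class WaterSlabSpec:
    """Diffusing water-oxygen slab; only scripted waters may permeate.

    Non-scripted waters perform random walks reflected at the box walls and
    at the leaflet planes bounding their own compartment, so they can never
    complete an ordered three-plane crossing — the scripted list is the exact
    flux ground truth.
    """

    n_waters: int = 200
    membrane: MembraneGeometry = field(
        default_factory=lambda: MembraneGeometry(-15.0, 15.0))
    box_xy: float = 40.0              # A
    box_z: tuple[float, float] = (-30.0, 30.0)
    diffusion_step_sigma: float = 0.5  # A per frame, per coordinate
    scripted_events: list[ScriptedEvent] = field(default_factory=list)
    frame_interval: float = 0.01      # ns
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.box_z
        if not (lo < self.membrane.inner_leaflet_z
                and self.membrane.outer_leaflet_z < hi):
            raise ValueError("membrane planes must lie inside the box in z")
        ids = [e.water_id for e in self.scripted_events]
        if len(set(ids)) != len(ids):
            raise ValueError("at most one scripted event per water")
        for e in self.scripted_events:
            if not (0 <= e.water_id < self.n_waters):
                raise ValueError(f"scripted water_id {e.water_id} out of range")


def _first_frame_past(z0: float, z1: float, i0: int, i1: int, plane: float,
                      upward: bool) -> int:
    """First frame index with z strictly past ``plane`` on a linear path.

    Closed-form on z(i) = z0 + (z1 - z0) * (i - i0) / (i1 - i0); used to plant
    ground-truth crossing frames independently of the event tracker.
    """
    slope = (z1 - z0) / (i1 - i0)
    frac = (plane - z0) / slope
    i = i0 + int(np.floor(frac)) + 1
    # guard against exact-equality landings
    while True:
        z = z0 + slope * (i - i0)
        zprev = z0 + slope * (i - 1 - i0)
        ok = (z > plane >= zprev) if upward else (z < plane <= zprev)
        if ok:
            return i
        i += 1 if ((z <= plane) == upward) else -1


def make_water_slab(spec: WaterSlabSpec, n_frames: int
                    ) -> tuple[Trajectory, AtomTable, list[PermeationEvent]]:
    """Generate the slab trajectory and its exact permeation ground truth."""
    for e in spec.scripted_events:
        if e.end_frame >= n_frames:
            raise GenerationError(
                f"scripted event for water {e.water_id} ends after the trajectory")
    rng = np.random.default_rng(spec.seed)
    mem = spec.membrane
    zlo, zhi = spec.box_z
    planes = mem.planes
    margin = 3.7  # A beyond the terminal planes for scripted start/end points

    scripted = {e.water_id: e for e in spec.scripted_events}

    # compartment bounds: 0 below inner, 1 between leaflets, 2 above outer
    comp_bounds = [(zlo, mem.inner_leaflet_z),
                   (mem.inner_leaflet_z, mem.outer_leaflet_z),
                   (mem.outer_leaflet_z, zhi)]

    n = spec.n_waters
    x = rng.uniform(0.0, spec.box_xy, size=(n, 2))
    comp = rng.integers(0, 3, size=n)
    z = np.array([rng.uniform(*comp_bounds[c]) for c in comp])

    # scripted waters start in their origin compartment at the scripted z
    for wid, e in scripted.items():
        if e.direction == "efflux":
            z[wid] = mem.inner_leaflet_z - margin
            comp[wid] = 0
        else:
            z[wid] = mem.outer_leaflet_z + margin
            comp[wid] = 2

    ground_truth = []
    path_z = {}  # water_id -> precomputed deterministic z over event window
    for wid, e in scripted.items():
        if e.direction == "efflux":
            z0 = mem.inner_leaflet_z - margin
            z1 = mem.outer_leaflet_z + margin
            first, third = planes[0], planes[2]
            upward = True
        else:
            z0 = mem.outer_leaflet_z + margin
            z1 = mem.inner_leaflet_z - margin
            first, third = planes[2], planes[0]
            upward = False
        i_start = _first_frame_past(z0, z1, e.start_frame, e.end_frame, first, upward)
        i_end = _first_frame_past(z0, z1, e.start_frame, e.end_frame, third, upward)
        ground_truth.append(PermeationEvent(
            water_id=wid, direction=e.direction,
            t_start=i_start * spec.frame_interval,
            t_end=i_end * spec.frame_interval))
        idx = np.arange(e.start_frame, e.end_frame + 1)
        path_z[wid] = z0 + (z1 - z0) * (idx - e.start_frame) / (e.end_frame - e.start_frame)

    coords = np.empty((n_frames, n, 3))
    for i in range(n_frames):
        if i > 0:
            step = rng.normal(0.0, spec.diffusion_step_sigma, size=(n, 3))
            x = x + step[:, :2]
            x = np.where(x < 0, -x, x)
            x = np.where(x > spec.box_xy, 2 * spec.box_xy - x, x)
            znew = z + step[:, 2]
            for c in range(3):
                mask = comp == c
                lo, hi = comp_bounds[c]
                zc = znew[mask]
                # reflect into the compartment (walk steps are << width)
                zc = np.where(zc < lo, 2 * lo - zc, zc)
                zc = np.where(zc > hi, 2 * hi - zc, zc)
                znew[mask] = zc
            z = znew
        # scripted overrides
        for wid, e in scripted.items():
            if e.start_frame <= i <= e.end_frame:
                z[wid] = path_z[wid][i - e.start_frame]
                if i == e.end_frame:
                    comp[wid] = 2 if e.direction == "efflux" else 0
            elif i > e.end_frame:
                pass  # random walk in destination compartment
            else:
                # hold origin-side start position until the event begins
                z[wid] = (mem.inner_leaflet_z - margin if e.direction == "efflux"
                          else mem.outer_leaflet_z + margin)
        coords[i, :, 0] = x[:, 0]
        coords[i, :, 1] = x[:, 1]
        coords[i, :, 2] = z

    atoms = AtomTable.from_columns(
        ["O"] * n, np.arange(1, n + 1), ["HOH"] * n)
    box = np.array([spec.box_xy, spec.box_xy, zhi - zlo])
    frames = [Frame(time=i * spec.frame_interval, coords=coords[i], box=box)
              for i in range(n_frames)]
    traj = Trajectory(frames, spec.frame_interval)
    ground_truth.sort(key=lambda ev: (ev.t_end, ev.water_id))
    return traj, atoms, ground_truth


# ---------------------------------------------------------------------------
# Two-state feature ensembles (planted discriminative distance pairs)
# ---------------------------------------------------------------------------

@dataclass
class FeatureEnsembleSpec:
    """Independent per-pair Gaussian distances in two states.

    ``informative_pairs`` get different means in the two states (one side a
    contact, the other not); all other pairs share a state-independent mean.
    """

    n_pairs: int = 90
    n_frames_per_state: int = 5000
    informative_pairs: tuple[int, ...] = (0, 7, 21, 42, 63)
    mean_contact: float = 8.0         # A, informative mean in the contact state
    mean_apart: float = 12.0          # A, informative mean in the other state
    uninformative_mean: float = 11.0  # A, shared by uninformative pairs
    sigma: float = 0.5                # A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(not 0 <= p < self.n_pairs for p in self.informative_pairs):
            raise ValueError("informative_pairs out of range")

    def state_means(self) -> tuple[np.ndarray, np.ndarray]:
        mu_a = np.full(self.n_pairs, self.uninformative_mean)
        mu_b = np.full(self.n_pairs, self.uninformative_mean)
        info = np.array(self.informative_pairs, dtype=int)
        # alternate which state holds the contact so both filter directions occur
        for j, p in enumerate(info):
            if j % 2 == 0:
                mu_a[p], mu_b[p] = self.mean_contact, self.mean_apart
            else:
                mu_a[p], mu_b[p] = self.mean_apart, self.mean_contact
        return mu_a, mu_b


def make_feature_ensemble(spec: FeatureEnsembleSpec
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (features_state_a, features_state_b, informative_indices)."""
    rng = np.random.default_rng(spec.seed)
    mu_a, mu_b = spec.state_means()
    fa = rng.normal(mu_a, spec.sigma, size=(spec.n_frames_per_state, spec.n_pairs))
    fb = rng.normal(mu_b, spec.sigma, size=(spec.n_frames_per_state, spec.n_pairs))
    return fa, fb, np.array(sorted(spec.informative_pairs), dtype=int)


# ---------------------------------------------------------------------------
# Langevin dynamics on analytic potentials
# ---------------------------------------------------------------------------

@dataclass
class PotentialSpec:
    """Analytic test potential with closed-form minima and barrier.

    Forms: ``flat`` (zero force, reflecting walls at ``bounds``),
    ``harmonic`` (0.5*k*x^2), ``double_well_1d`` (h*(x^2-1)^2 + tilt*x),
    ``double_well_2d`` (adds 0.5*ky*y^2). Energies in kcal/mol.
    """

    form: str = "double_well_1d"
    h: float = 5.0                    # kcal/mol, double-well barrier
    k: float = 1.0                    # kcal/mol, harmonic stiffness
    ky: float = 2.0                   # kcal/mol, 2-D transverse stiffness
    tilt: float = 0.0                 # kcal/mol per unit x
    bounds: tuple[float, float] = (-2.0, 2.0)
    kT: float = 0.0019872041 * 310.0  # kcal/mol at 310 K

    _FORMS = ("flat", "harmonic", "double_well_1d", "double_well_2d")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"unknown potential form {self.form!r}")

    @property
    def ndim(self) -> int:
        return 2 if self.form == "double_well_2d" else 1

    def energy(self, x, y=None):
        x = np.asarray(x, dtype=float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            return 0.5 * self.k * x ** 2
        u = self.h * (x ** 2 - 1.0) ** 2 + self.tilt * x
        if self.form == "double_well_2d":
            u = u + 0.5 * self.ky * np.asarray(y, dtype=float) ** 2
        return u

    def barrier_height(self) -> float:
        """Energy barrier from the lower well to the top (untilted: h)."""
        if not self.form.startswith("double_well"):
            raise ValueError("barrier defined only for double wells")
        xs = np.roots([4 * self.h, 0.0, -4 * self.h, self.tilt])
        xs = np.sort(xs[np.isreal(xs)].real)
        if len(xs) != 3:
            raise ValueError("potential has no barrier for this tilt")
        u = self.energy(xs)
        return float(u[1] - min(u[0], u[2]))

    def form_code(self) -> int:
        return {"flat": _integrators.FORM_FLAT,
                "harmonic": _integrators.FORM_HARMONIC,
                "double_well_1d": _integrators.FORM_DOUBLE_WELL,
                "double_well_2d": _integrators.FORM_DOUBLE_WELL}[self.form]


def langevin_trajectory(spec: PotentialSpec, n_steps: int, dt: float = 0.002,
                        friction: float = 1.0, seed: int = 0,
                        x0: Optional[np.ndarray] = None,
                        record_stride: int = 1) -> np.ndarray:
    """Unbiased overdamped Euler–Maruyama run; returns recorded positions.

    1-D forms return shape (n_recorded,), the 2-D form (n_recorded, 2).
    Stability requires dt * omega^2 / friction << 1 for the stiffest
    curvature omega^2 of the potential; divergence raises RuntimeError.
    """
    rng = np.random.default_rng(seed)
    empty = np.zeros(0)
    if spec.ndim == 1:
        x = float(x0) if x0 is not None else (
            -1.0 if spec.form.startswith("double_well") else 0.0)
        out_x = np.empty(n_steps)
        out_b = np.empty(n_steps)
        reflect = spec.form == "flat"
        status, _ = _integrators.integrate_1d(
            x, rng.standard_normal(n_steps), dt, spec.kT, friction,
            spec.form_code(), spec.h, spec.k, spec.tilt,
            spec.bounds[0], spec.bounds[1], reflect,
            empty, empty, 0.0, 1.0, out_x, out_b)
        if status:
            raise RuntimeError("Langevin integration diverged; reduce dt")
        return out_x[::record_stride].copy()
    xy0 = np.asarray(x0, dtype=float) if x0 is not None else np.array([-1.0, 0.0])
    out_xy = np.empty((n_steps, 2))
    out_b = np.empty(n_steps)
    empty2 = np.zeros((0, 0))
    status, _, _ = _integrators.integrate_2d(
        xy0[0], xy0[1], rng.standard_normal((n_steps, 2)), dt, spec.kT,
        friction, spec.h, spec.ky, spec.tilt,
        empty2, empty2, empty2, 0.0, 1.0, 0.0, 1.0, out_xy, out_b)
    if status:
        raise RuntimeError("Langevin integration diverged; reduce dt")
    return out_xy[::record_stride].copy()
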