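"""Core data model and I/O for transporter trajectory analysis.

Containers for atom tables, frames, trajectories, transmembrane-helix
annotations and membrane geometry, plus readers/writers for the plain-text
formats the toolkit exchanges (PDB topologies, multi-frame XYZ or multi-model
PDB trajectories, YAML helix annotations, TSV tables).

Conventions
-----------
* Coordinates are in Angstrom, times in ns.
* The membrane normal is +Z and the extracellular side is at larger Z.
  Every plane definition in the toolkit inherits this.
* Trajectories are assumed pre-imaged (molecules whole); no periodic
  re-imaging is performed.
* Residue numbering follows the input file verbatim.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "AtomTable",
    "Frame",
    "Trajectory",
    "HelixSegment",
    "TMTopology",
    "MembraneGeometry",
    "StateLabel",
    "LabeledEnsemble",
    "FormatError",
    "BONDI_RADII",
    "read_pdb",
    "read_trajectory",
    "write_pdb",
    "write_xyz",
    "read_helix_yaml",
    "write_helix_yaml",
    "center_of_mass",
    "select_backbone",
]

# Bondi van der Waals radii (A) by element; fallback 1.7 A (carbon-like).
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39,
}

BACKBONE_NAMES = ("N", "CA", "C", "O")

# Atomic masses for the optional mass-weighted center of mass.
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
                 "P": 30.974, "NA": 22.990, "K": 39.098, "CL": 35.45}


class FormatError(ValueError):
    """A structured input file violated the expected format."""


def _element_from_name(name: str) -> str:
    """Guess the element from a PDB-style atom name."""
    stripped = name.strip()
    if not stripped:
        return "C"
    # Two-letter elements that appear in this toolkit's inputs.
    upper = stripped.upper()
    for two in ("CL", "NA", "MG", "ZN", "BR"):
        if upper.startswith(two) and len(stripped) <= 2:
            return two
    head = stripped.lstrip("0123456789")
    return head[0].upper() if head else "C"


@dataclass
class AtomTable:
    """Column-oriented atom metadata shared by all frames of a system."""

    atom_index: np.ndarray      # int, unique, contiguous from 0
    atom_name: np.ndarray       # str
    residue_index: np.ndarray   # int
    residue_name: np.ndarray    # str
    is_backbone: np.ndarray     # bool
    vdw_radius: np.ndarray      # float, A
    element: np.ndarray         # str

    def __post_init__(self) -> None:
        n = len(self.atom_index)
        idx = np.asarray(self.atom_index)
        if n and (idx.min() != 0 or not np.array_equal(np.sort(idx), np.arange(n))):
            raise ValueError("atom_index must be unique and contiguous from 0")
        if np.any(np.asarray(self.vdw_radius) <= 0):
            raise ValueError("vdw_radius must be positive")

    def __len__(self) -> int:
        return len(self.atom_index)

    @classmethod
    def from_columns(cls, atom_name, residue_index, residue_name,
                     vdw_radius=None, element=None) -> "AtomTable":
        atom_name = np.asarray(atom_name, dtype=object)
        n = len(atom_name)
        residue_index = np.asarray(residue_index, dtype=int)
        residue_name = np.asarray(residue_name, dtype=object)
        if element is None:
            element = np.array([_element_from_name(a) for a in atom_name], dtype=object)
        else:
            element = np.asarray(element, dtype=object)
        if vdw_radius is None:
            vdw_radius = np.array([BONDI_RADII.get(e, 1.70) for e in element])
        else:
            vdw_radius = np.asarray(vdw_radius, dtype=float)
        is_backbone = np.isin(np.array([a.strip() for a in atom_name]), BACKBONE_NAMES)
        return cls(np.arange(n), atom_name, residue_index, residue_name,
                   is_backbone, vdw_radius, element)

    def select(self, *, names: Optional[Iterable[str]] = None,
               residues: Optional[Iterable[int]] = None,
               backbone_only: bool = False) -> np.ndarray:
        """Return atom indices matching all given criteria."""
        mask = np.ones(len(self), dtype=bool)
        if names is not None:
            mask &= np.isin(np.array([a.strip() for a in self.atom_name]), list(names))
        if residues is not None:
            mask &= np.isin(self.residue_index, np.asarray(list(residues)))
        if backbone_only:
            mask &= self.is_backbone
        return np.nonzero(mask)[0]


@dataclass
class Frame:
    """One snapshot: per-atom coordinates plus box and time stamp."""

    time: float                 # ns
    coords: np.ndarray          # (n_atoms, 3), A
    box: np.ndarray = field(default_factory=lambda: np.array([100.0, 100.0, 100.0]))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive lengths")


class Trajectory:
    """Ordered frame sequence with a uniform frame interval (ns)."""

    def __init__(self, frames: Sequence[Frame], frame_interval: Optional[float] = None):
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        times = np.array([f.time for f in frames])
        if len(times) > 1:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.ptp(dts) > 1e-9:
                raise ValueError("frame interval must be uniform within 1e-9 ns")
            inferred = float(dts[0])
            if frame_interval is not None and abs(frame_interval - inferred) > 1e-9:
                raise ValueError("frame_interval inconsistent with frame times")
            frame_interval = inferred
        elif frame_interval is None:
            frame_interval = 1.0
        self.frames = list(frames)
        self.frame_interval = float(frame_interval)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coords_array(self) -> np.ndarray:
        """Stack all frame coordinates into (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class HelixSegment:
    """A transmembrane helix: residue range plus tip and bend windows.

    Tips are the short terminal residue stretches whose backbone centers of
    mass anchor the angle metrics; ``bend_window`` marks where a kinked helix
    bends (needed for the intrahelical angle).
    """

    helix_id: str
    residue_range: tuple[int, int]          # inclusive
    extracellular_tip: tuple[int, int]      # inclusive
    intracellular_tip: tuple[int, int]      # inclusive
    bend_window: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        for name, win in (("extracellular_tip", self.extracellular_tip),
                          ("intracellular_tip", self.intracellular_tip),
                          ("bend_window", self.bend_window)):
            if win is None:
                continue
            if not (lo <= win[0] <= win[1] <= hi):
                raise ValueError(f"{name} {win} not inside residue_range {self.residue_range}")
        ec, ic = self.extracellular_tip, self.intracellular_tip
        if max(ec[0], ic[0]) <= min(ec[1], ic[1]):
            raise ValueError("tip windows must be disjoint")

    def residues(self) -> range:
        return range(self.residue_range[0], self.residue_range[1] + 1)


@dataclass
class TMTopology:
    """Atom table plus helix annotations and the static/mobile partition."""

    atoms: AtomTable
    helices: list[HelixSegment]
    static_domain: list[str]
    mobile_bundle: list[str]
    # Helices whose intracellular tips anchor the bundle-angle reference
    # (the intracellular extreme of the static scaffold).
    static_anchor: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [h.helix_id for h in self.helices]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate helix ids")
        ranges = sorted(h.residue_range for h in self.helices)
        for (a, b), (c, d) in zip(ranges, ranges[1:]):
            if c <= b:
                raise ValueError("helix residue ranges must be pairwise disjoint")
        if set(self.static_domain) & set(self.mobile_bundle):
            raise ValueError("static_domain and mobile_bundle must be disjoint")
        for hid in self.static_domain + self.mobile_bundle + self.static_anchor:
            if hid not in ids:
                raise ValueError(f"unknown helix id {hid!r}")
        if not self.static_anchor:
            self.static_anchor = list(self.static_domain[:2])

    def helix(self, helix_id: str) -> HelixSegment:
        for h in self.helices:
            if h.helix_id == helix_id:
                return h
        raise KeyError(helix_id)


@dataclass
class MembraneGeometry:
    """Z positions of the leaflet planes and the bilayer midplane (A)."""

    inner_leaflet_z: float
    outer_leaflet_z: float
    midplane_z: Optional[float] = None

    def __post_init__(self) -> None:
        if self.midplane_z is None:
            self.midplane_z = 0.5 * (self.inner_leaflet_z + self.outer_leaflet_z)
        if not (self.inner_leaflet_z < self.midplane_z < self.outer_leaflet_z):
            raise ValueError("planes must satisfy inner < midplane < outer")

    @property
    def planes(self) -> np.ndarray:
        """The three crossing planes in ascending Z order."""
        return np.array([self.inner_leaflet_z, self.midplane_z, self.outer_leaflet_z])


class StateLabel(Enum):
    IO = "IO"          # inward open
    OCC = "OCC"        # occluded
    OO = "OO"          # outward open
    UNKNOWN = "UNKNOWN"


@dataclass
class LabeledEnsemble:
    """Trajectory frames tagged with one conformational state label each."""

    frames: list[Frame]
    labels: list[StateLabel]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.labels):
            raise ValueError("one label per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    def subset(self, label: StateLabel) -> "LabeledEnsemble":
        pairs = [(f, l) for f, l in zip(self.frames, self.labels) if l is label]
        return LabeledEnsemble([p[0] for p in pairs], [p[1] for p in pairs])

    def coords_array(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | os.PathLike) -> tuple[AtomTable, Frame]:
    """Read a single-structure PDB file into an atom table and one frame.

    Backbone atoms are those named N, CA, C or O; van der Waals radii are
    assigned from the Bondi set by element inferred from the atom name.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    names, resids, resnames, xyz = [], [], [], []
    box = np.array([100.0, 100.0, 100.0])
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                except ValueError:
                    pass
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
                resid = int(line[22:26])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: unparseable ATOM record at line {lineno}") from exc
            names.append(line[12:16].strip())
            resids.append(resid)
            resnames.append(line[17:20].strip())
            xyz.append((x, y, z))
    if not names:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    table = AtomTable.from_columns(names, resids, resnames)
    return table, Frame(time=0.0, coords=np.array(xyz), box=box)


def read_trajectory(path: str | os.PathLike, atoms: AtomTable,
                    frame_interval: float = 1.0) -> Trajectory:
    """Read a multi-frame XYZ or multi-model PDB trajectory.

    Frame times are ``i * frame_interval`` (ns). Every frame must contain
    exactly ``len(atoms)`` coordinates.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        head = fh.read(512)
    if "MODEL" in head or head.lstrip().startswith(("ATOM", "HETATM", "CRYST1", "REMARK", "TITLE")):
        frames_xyz = _read_multimodel_pdb(path)
    else:
        frames_xyz = _read_multiframe_xyz(path)
    frames = []
    for i, coords in enumerate(frames_xyz):
        if len(coords) != len(atoms):
            raise FormatError(
                f"{path}: frame {i} has {len(coords)} atoms, expected {len(atoms)}")
        frames.append(Frame(time=i * frame_interval, coords=coords))
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return Trajectory(frames, frame_interval)


def _read_multiframe_xyz(path: str) -> list[np.ndarray]:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        coords = np.empty((n, 3))
        for j, ln in enumerate(block):
            parts = ln.split()
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: bad XYZ record at line {i + 3 + j}") from exc
        frames.append(coords)
        i += 2 + n
    return frames


def _read_multimodel_pdb(path: str) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                try:
                    current.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
                except (ValueError, IndexError) as exc:
                    raise FormatError(f"{path}: unparseable record at line {lineno}") from exc
            elif rec == "ENDMDL":
                frames.append(np.array(current))
                current = []
    if current:
        frames.append(np.array(current))
    return frames


def write_pdb(path: str | os.PathLike, atoms: AtomTable, frame: Frame) -> None:
    """Write one frame as a PDB file (fixed-column ATOM records)."""
    with open(path, "w") as fh:
        fh.write(f"CRYST1{frame.box[0]:9.3f}{frame.box[1]:9.3f}{frame.box[2]:9.3f}"
                 f"  90.00  90.00  90.00 P 1           1\n")
        for i in range(len(atoms)):
            name = str(atoms.atom_name[i])
            # PDB name column convention: left-pad 1-3 char names into cols 14-16
            name_field = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = frame.coords[i]
            fh.write(
                f"ATOM  {i + 1:5d} {name_field:<4s}{str(atoms.residue_name[i])[:3]:>4s} A"
                f"{int(atoms.residue_index[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {str(atoms.element[i]):>2s}\n")
        fh.write("END\n")


def write_xyz(path: str | os.PathLike, atoms: AtomTable, traj: Trajectory) -> None:
    """Write a trajectory as multi-frame XYZ (element symbol + coordinates)."""
    with open(path, "w") as fh:
        for k, frame in enumerate(traj):
            fh.write(f"{len(atoms)}\n")
            fh.write(f"frame {k} time_ns {frame.time:.6f}\n")
            for i in range(len(atoms)):
                x, y, z = frame.coords[i]
                fh.write(f"{str(atoms.element[i]):<2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


def write_helix_yaml(path: str | os.PathLike, topo: TMTopology) -> None:
    doc = {
        "helices": [
            {
                "helix_id": h.helix_id,
                "residue_range": list(h.residue_range),
                "extracellular_tip": list(h.extracellular_tip),
                "intracellular_tip": list(h.intracellular_tip),
                **({"bend_window": list(h.bend_window)} if h.bend_window else {}),
            }
            for h in topo.helices
        ],
        "static_domain": list(topo.static_domain),
        "mobile_bundle": list(topo.mobile_bundle),
        "static_anchor": list(topo.static_anchor),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_helix_yaml(path: str | os.PathLike, atoms: AtomTable) -> TMTopology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    helices = [
        HelixSegment(
            helix_id=h["helix_id"],
            residue_range=tuple(h["residue_range"]),
            extracellular_tip=tuple(h["extracellular_tip"]),
            intracellular_tip=tuple(h["intracellular_tip"]),
            bend_window=tuple(h["bend_window"]) if "bend_window" in h else None,
        )
        for h in doc["helices"]
    ]
    return TMTopology(atoms=atoms, helices=helices,
                      static_domain=list(doc.get("static_domain", [])),
                      mobile_bundle=list(doc.get("mobile_bundle", [])),
                      static_anchor=list(doc.get("static_anchor", [])))


# ---------------------------------------------------------------------------
# Selections and geometry primitives
# ---------------------------------------------------------------------------

def center_of_mass(frame: Frame, selection: np.ndarray,
                   atoms: Optional[AtomTable] = None,
                   mass_weighted: bool = False) -> np.ndarray:
    """Center of mass of a selection; unweighted (geometric) by default.

    The backbone atoms N/CA/C/O differ in mass by <33% and tip windows are
    symmetric, so the unweighted mean is the default; pass
    ``mass_weighted=True`` with an atom table for the mass-weighted variant.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    pts = frame.coords[selection]
    if not mass_weighted:
        return pts.mean(axis=0)
    if atoms is None:
        raise ValueError("mass_weighted=True requires the atom table")
    masses = np.array([ATOMIC_MASSES.get(e, 12.011) for e in atoms.element[selection]])
    return (pts * masses[:, None]).sum(axis=0) / masses.sum()


def select_backbone(topo: TMTopology, helix_id: str,
                    window: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Backbone atom indices of a helix, optionally restricted to a window."""
    helix = topo.helix(helix_id)
    lo, hi = helix.residue_range
    if window is None:
        window = (lo, hi)
    if not (lo <= window[0] <= window[1] <= hi):
        raise ValueError(f"window {window} outside helix {helix_id} range {helix.residue_range}")
    sel = topo.atoms.select(residues=range(window[0], window[1] + 1), backbone_only=True)
    if sel.size == 0:
        raise ValueError(f"no backbone atoms in window {window} of helix {helix_id}")
    return sel
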