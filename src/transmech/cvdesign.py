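"""Conformational collective-variable engineering.

Builds a discriminant CV separating two metastable conformations from
interhelical Calpha–Calpha distances: exhaustive pair extraction over the TM
helices, a three-stage filter (drop intra-helix pairs, keep adjacent-helix
pairs, keep contact-in-exactly-one-state pairs, drop pairs whose state means
are not separated beyond the noise), and a Fisher linear discriminant whose
projection is affinely normalized so the training-state means sit exactly at
-2.6 (inward-open) and +2.6 (outward-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .core import LabeledEnsemble, TMTopology, Trajectory

__all__ = [
    "PairCatalog", "FilterConfig", "CVModel",
    "extract_pairs", "pair_distances", "filter_pairs",
    "fit_discriminant_cv", "evaluate_cv", "write_colvar", "read_colvar",
]

ENDPOINT = 2.6  # normalized CV value of the training-state means (+/-)


@dataclass
class PairCatalog:
    """Calpha–Calpha pair metadata: atom indices and owning helices."""

    atom_i: np.ndarray     # int
    atom_j: np.ndarray     # int, atom_i < atom_j
    helix_i: np.ndarray    # str
    helix_j: np.ndarray    # str

    def __post_init__(self) -> None:
        if np.any(self.atom_i >= self.atom_j):
            raise ValueError("pairs must satisfy atom_i < atom_j")
        key = self.atom_i.astype(np.int64) << 32 | self.atom_j.astype(np.int64)
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate pairs in catalog")

    def __len__(self) -> int:
        return len(self.atom_i)

    @property
    def interhelix(self) -> np.ndarray:
        return self.helix_i != self.helix_j

    def subset(self, idx: np.ndarray) -> "PairCatalog":
        return PairCatalog(self.atom_i[idx], self.atom_j[idx],
                           self.helix_i[idx], self.helix_j[idx])


@dataclass
class FilterConfig:
    """Three-stage filter settings.

    ``contact_cutoff``: a pair is a contact in a state when its mean distance
    is below this (10 A). ``sd_multiplier``: pairs whose state means differ by
    less than this many SDs are dropped (2). ``adjacency_rule`` defines which
    helix pairs count as adjacent; ``spatial_adjacent`` keeps helix pairs
    whose minimum mean Calpha distance is below ``spatial_adjacency_cutoff``
    in either state.
    """

    contact_cutoff: float = 10.0
    sd_multiplier: float = 2.0
    adjacency_rule: str = "spatial_adjacent"   # | sequence_adjacent | all_interhelix
    spatial_adjacency_cutoff: float = 12.0
    sd_combination: str = "max"                # | pooled | either

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.sd_multiplier <= 0:
            raise ValueError("cutoff and sd_multiplier must be positive")
        if self.adjacency_rule not in ("spatial_adjacent", "sequence_adjacent",
                                       "all_interhelix"):
            raise ValueError(f"unknown adjacency_rule {self.adjacency_rule!r}")


@dataclass
class CVModel:
    """Linear discriminant over a distance feature set, normalized to +/-2.6."""

    catalog: Optional[PairCatalog]
    weights: np.ndarray          # raw discriminant direction, one per pair
    affine_scale: float
    affine_shift: float
    separation: float            # |projected mean gap| / pooled projected SD
    endpoint_targets: tuple[float, float] = (-ENDPOINT, ENDPOINT)

    def project(self, features: np.ndarray) -> np.ndarray:
        """Normalized CV values for a (n_frames, n_pairs) feature matrix."""
        raw = np.asarray(features) @ self.weights
        return self.affine_scale * raw + self.affine_shift


def extract_pairs(topo: TMTopology) -> PairCatalog:
    """All unordered Calpha pairs whose atoms lie in annotated TM helices.

    Intra-helix pairs are included but flagged via ``helix_i == helix_j``;
    the filter's first stage removes them.
    """
    ca_idx, ca_helix = [], []
    for h in topo.helices:
        sel = topo.atoms.select(names=["CA"], residues=h.residues())
        if sel.size == 0:
            raise ValueError(f"helix {h.helix_id} has no Calpha atoms")
        ca_idx.extend(sel.tolist())
        ca_helix.extend([h.helix_id] * sel.size)
    ca_idx = np.array(ca_idx)
    ca_helix = np.array(ca_helix, dtype=object)
    ii, jj = np.triu_indices(len(ca_idx), k=1)
    ai, aj = ca_idx[ii], ca_idx[jj]
    hi, hj = ca_helix[ii], ca_helix[jj]
    swap = ai > aj
    ai[swap], aj[swap] = aj[swap], ai[swap]
    hi[swap], hj[swap] = hj[swap], hi[swap]
    return PairCatalog(ai, aj, hi, hj)


def pair_distances(frames: Trajectory | LabeledEnsemble | Sequence,
                   catalog: PairCatalog) -> np.ndarray:
    """Per-frame Euclidean distances, shape (n_frames, n_pairs)."""
    frames = frames.frames if hasattr(frames, "frames") else list(frames)
    out = np.empty((len(frames), len(catalog)))
    for k, f in enumerate(frames):
        d = f.coords[catalog.atom_i] - f.coords[catalog.atom_j]
        out[k] = np.sqrt((d * d).sum(axis=1))
    return out


def _adjacent_mask(catalog: PairCatalog, dist_a: np.ndarray, dist_b: np.ndarray,
                   cfg: FilterConfig) -> np.ndarray:
    if cfg.adjacency_rule == "all_interhelix":
        return np.ones(len(catalog), dtype=bool)
    if cfg.adjacency_rule == "sequence_adjacent":
        num_i = np.array([int(str(h).lstrip("TM")) for h in catalog.helix_i])
        num_j = np.array([int(str(h).lstrip("TM")) for h in catalog.helix_j])
        return np.abs(num_i - num_j) == 1
    # spatial adjacency: helix pairs that come close in either state
    mu = np.minimum(dist_a.mean(axis=0), dist_b.mean(axis=0))
    keys = np.array([f"{i}|{j}" for i, j in zip(catalog.helix_i, catalog.helix_j)],
                    dtype=object)
    adjacent_keys = set()
    for key in np.unique(keys):
        if mu[keys == key].min() < cfg.spatial_adjacency_cutoff:
            adjacent_keys.add(key)
    return np.array([k in adjacent_keys for k in keys])


def filter_pairs(catalog: PairCatalog, dist_a: np.ndarray, dist_b: np.ndarray,
                 cfg: Optional[FilterConfig] = None
                 ) -> tuple[PairCatalog, np.ndarray]:
    """Apply the three-stage filter; returns (kept catalog, kept indices).

    Stages, in order: (1) drop intra-helix pairs; (2) keep only
    adjacent-helix pairs; (3) keep pairs that are a contact (mean distance
    below the cutoff) in exactly one state; (4) drop pairs whose state means
    lie within ``sd_multiplier`` standard deviations of each other.
    """
    cfg = cfg or FilterConfig()
    if dist_a.shape[0] < 2 or dist_b.shape[0] < 2:
        raise ValueError("need at least 2 frames per state")
    if dist_a.shape[1] != len(catalog) or dist_b.shape[1] != len(catalog):
        raise ValueError("distance matrices do not match catalog size")

    keep = catalog.interhelix.copy()                       # stage 1
    keep &= _adjacent_mask(catalog, dist_a, dist_b, cfg)   # stage 2

    mu_a, mu_b = dist_a.mean(axis=0), dist_b.mean(axis=0)
    contact_a = mu_a < cfg.contact_cutoff
    contact_b = mu_b < cfg.contact_cutoff
    keep &= contact_a != contact_b                         # stage 3

    sd_a = dist_a.std(axis=0, ddof=1)
    sd_b = dist_b.std(axis=0, ddof=1)
    if cfg.sd_combination == "max":
        sd = np.maximum(sd_a, sd_b)
    elif cfg.sd_combination == "pooled":
        sd = np.sqrt(0.5 * (sd_a ** 2 + sd_b ** 2))
    elif cfg.sd_combination == "either":
        sd = np.minimum(sd_a, sd_b)
    else:
        raise ValueError(f"unknown sd_combination {cfg.sd_combination!r}")
    keep &= np.abs(mu_a - mu_b) >= cfg.sd_multiplier * sd  # stage 4

    idx = np.nonzero(keep)[0]
    return catalog.subset(idx), idx


def fit_discriminant_cv(features_a: np.ndarray, features_b: np.ndarray,
                        mode: str = "fisher_linear",
                        catalog: Optional[PairCatalog] = None,
                        ridge_factor: float = 1e-6) -> CVModel:
    """Fit the discriminant CV from per-state feature matrices.

    ``fisher_linear`` solves w proportional to Sw^-1 (mu_b - mu_a) with a ridge
    of ``ridge_factor * trace(Sw)/dim`` added to the pooled within-class
    covariance for stability, then maps the projected state means exactly to
    -2.6 (state A) and +2.6 (state B).
    """
    if mode == "deep":
        raise NotImplementedError(
            "the nonlinear (neural feature map) discriminant requires an "
            "optional torch dependency and is not built; use 'fisher_linear'")
    if mode != "fisher_linear":
        raise ValueError(f"unknown mode {mode!r}")
    fa = np.asarray(features_a, dtype=float)
    fb = np.asarray(features_b, dtype=float)
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need at least 2 frames per state")
    if fa.shape[1] != fb.shape[1] or fa.shape[1] < 1:
        raise ValueError("feature matrices must share at least one column")

    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    sw = np.cov(fa, rowvar=False, ddof=1) + np.cov(fb, rowvar=False, ddof=1)
    sw = np.atleast_2d(sw) * 0.5
    dim = sw.shape[0]
    ridge = ridge_factor * np.trace(sw) / dim
    if ridge == 0.0:
        ridge = ridge_factor  # zero-variance features: fall back to absolute ridge
    w = np.linalg.solve(sw + ridge * np.eye(dim), mu_b - mu_a)

    proj_a, proj_b = fa @ w, fb @ w
    gap = proj_b.mean() - proj_a.mean()
    pooled_sd = np.sqrt(0.5 * (proj_a.var(ddof=1) + proj_b.var(ddof=1)))
    separation = abs(gap) / pooled_sd if pooled_sd > 0 else np.inf
    if abs(gap) < 1e-12 or (np.isfinite(separation) and separation < 0.1):
        warnings.warn("state distributions are barely separated; CV is "
                      "ill-defined", stacklevel=2)
    if abs(gap) < 1e-300:
        scale, shift = 1.0, 0.0
    else:
        scale = 2 * ENDPOINT / gap
        shift = -ENDPOINT - scale * proj_a.mean()
    return CVModel(catalog=catalog, weights=w, affine_scale=scale,
                   affine_shift=shift, separation=float(separation))


def evaluate_cv(model: CVModel, frames: Trajectory | LabeledEnsemble | Sequence
                ) -> np.ndarray:
    """Normalized CV time series for a trajectory (needs the model's catalog)."""
    if model.catalog is None:
        raise ValueError("model has no pair catalog; project features directly")
    return model.project(pair_distances(frames, model.catalog))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_colvar(path, times: np.ndarray, columns: dict[str, np.ndarray]) -> None:
    """Write a COLVAR-style whitespace table with a #! FIELDS header."""
    names = ["time"] + list(columns)
    arrays = [np.asarray(times)] + [np.asarray(v) for v in columns.values()]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for row in zip(*arrays):
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_colvar(path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["#!", "FIELDS"]:
            raise ValueError(f"{path}: not a COLVAR file (missing #! FIELDS)")
        names = header[2:]
        data = np.loadtxt(fh, ndmin=2)
    return {n: data[:, k] for k, n in enumerate(names)}


def save_cv_model(path, model: CVModel) -> None:
    doc = {
        "endpoint_targets": list(model.endpoint_targets),
        "affine_scale": float(model.affine_scale),
        "affine_shift": float(model.affine_shift),
        "separation": float(model.separation),
        "weights": [float(w) for w in model.weights],
    }
    if model.catalog is not None:
        doc["pairs"] = [
            {"atom_i": int(i), "atom_j": int(j), "helix_i": str(hi), "helix_j": str(hj)}
            for i, j, hi, hj in zip(model.catalog.atom_i, model.catalog.atom_j,
                                    model.catalog.helix_i, model.catalog.helix_j)]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_cv_model(path) -> CVModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    catalog = None
    if "pairs" in doc:
        catalog = PairCatalog(
            np.array([p["atom_i"] for p in doc["pairs"]]),
            np.array([p["atom_j"] for p in doc["pairs"]]),
            np.array([p["helix_i"] for p in doc["pairs"]], dtype=object),
            np.array([p["helix_j"] for p in doc["pairs"]], dtype=object))
    return CVModel(catalog=catalog, weights=np.array(doc["weights"]),
                   affine_scale=doc["affine_scale"], affine_shift=doc["affine_shift"],
                   separation=doc["separation"],
                   endpoint_targets=tuple(doc["endpoint_targets"]))
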