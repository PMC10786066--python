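"""Mechanism metrics: bundle angle, intrahelical kink, vertical translation,
Kabsch superposition and distance statistics.

These metrics discriminate the two classic alternating-access mechanisms:
a *rocking bundle* (a mobile helix pair tilts against a static scaffold,
large angle change, no vertical motion) versus an *elevator* (the transport
domain translates along the membrane normal). All angles are in degrees and
all lengths in Angstrom; the membrane normal is +Z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (Frame, LabeledEnsemble, TMTopology, Trajectory,
                   center_of_mass, select_backbone)

__all__ = [
    "AngleSeries", "MechanismReport",
    "bundle_angle", "kink_angle", "angle_series",
    "vertical_translation", "superpose_kabsch",
    "mechanism_verdict", "distance_stats",
]


@dataclass
class AngleSeries:
    times: np.ndarray
    angles_deg: np.ndarray
    state_means: dict  # label -> (mean, sd)


@dataclass
class MechanismReport:
    delta_alpha_deg: float
    delta_z: float
    verdict: str                       # rocking_bundle | elevator | mixed | indeterminate
    alpha_threshold_deg: float
    z_threshold: float


def _vec_angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-6 or nv < 1e-6:
        raise ValueError("degenerate geometry: zero-length angle arm")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _tip_com(frame: Frame, topo: TMTopology, helix_ids: Sequence[str],
             which: str) -> np.ndarray:
    sels = []
    for hid in helix_ids:
        h = topo.helix(hid)
        win = h.extracellular_tip if which == "ec" else h.intracellular_tip
        sels.append(select_backbone(topo, hid, win))
    return center_of_mass(frame, np.concatenate(sels))


def bundle_angle(frame: Frame, topo: TMTopology) -> float:
    """Tilt of the mobile bundle against the static intracellular anchor.

    The angle is taken at vertex B between B->A and B->C, where A and B are
    the backbone-tip centers of mass of the mobile bundle (extracellular and
    intracellular respectively) and C is the intracellular tip COM of the
    static anchor helices. The vertex placement (at the mobile intracellular
    COM) reads the motion as a pure bundle rotation about its intracellular
    pivot.
    """
    a = _tip_com(frame, topo, topo.mobile_bundle, "ec")
    b = _tip_com(frame, topo, topo.mobile_bundle, "ic")
    c = _tip_com(frame, topo, topo.static_anchor, "ic")
    return _vec_angle(a - b, c - b)


def kink_angle(frame: Frame, topo: TMTopology, helix_id: str) -> float:
    """Intrahelical angle at the bend: 180 deg for a straight helix."""
    helix = topo.helix(helix_id)
    if helix.bend_window is None:
        raise ValueError(f"helix {helix_id} has no bend_window")
    vertex = center_of_mass(frame, select_backbone(topo, helix_id, helix.bend_window))
    ic = center_of_mass(frame, select_backbone(topo, helix_id, helix.intracellular_tip))
    ec = center_of_mass(frame, select_backbone(topo, helix_id, helix.extracellular_tip))
    return _vec_angle(ic - vertex, ec - vertex)


def angle_series(traj_or_frames, topo: TMTopology, kind: str = "bundle",
                 helix_id: Optional[str] = None,
                 labels=None) -> AngleSeries:
    """Per-frame angle series with optional per-state mean +/- SD (sample SD)."""
    frames = list(traj_or_frames)
    if kind == "bundle":
        vals = np.array([bundle_angle(f, topo) for f in frames])
    elif kind == "kink":
        vals = np.array([kink_angle(f, topo, helix_id) for f in frames])
    else:
        raise ValueError("kind must be 'bundle' or 'kink'")
    times = np.array([f.time for f in frames])
    means = {}
    if labels is not None:
        for lab in set(labels):
            sub = vals[np.array([l is lab for l in labels])]
            means[lab] = (float(sub.mean()), float(sub.std(ddof=1)) if len(sub) > 1 else 0.0)
    return AngleSeries(times, vals, means)


def _domain_com_z(frame: Frame, topo: TMTopology, helix_ids: Sequence[str]) -> float:
    sels = [select_backbone(topo, hid) for hid in helix_ids]
    return float(center_of_mass(frame, np.concatenate(sels))[2])


def vertical_translation(ensemble_a: LabeledEnsemble, ensemble_b: LabeledEnsemble,
                         topo: TMTopology, mode: str = "pivot") -> float:
    """Elevator test: state-mean difference of the mobile bundle's Z offset.

    Returned is mean(state B) - mean(state A), positive toward the
    extracellular side (+Z). The default ``pivot`` observable tracks the
    mobile bundle's intracellular-tip backbone COM against the static-domain
    COM: an elevator motion translates the whole bundle including its
    membrane anchor, while a pure rocking rotation about that anchor leaves
    it in place (a whole-helix COM would drop slightly under tilt by the
    cosine foreshortening, which is not an elevator signal). ``mode='full'``
    uses the whole mobile-bundle backbone COM instead.
    """
    if mode == "pivot":
        def mobile_z(f: Frame) -> float:
            sels = [select_backbone(topo, hid, topo.helix(hid).intracellular_tip)
                    for hid in topo.mobile_bundle]
            return float(center_of_mass(f, np.concatenate(sels))[2])
    elif mode == "full":
        def mobile_z(f: Frame) -> float:
            return _domain_com_z(f, topo, topo.mobile_bundle)
    else:
        raise ValueError("mode must be 'pivot' or 'full'")

    def series(ens: LabeledEnsemble) -> np.ndarray:
        if len(ens) == 0:
            raise ValueError("empty ensemble")
        return np.array([mobile_z(f) - _domain_com_z(f, topo, topo.static_domain)
                         for f in ens.frames])

    return float(series(ensemble_b).mean() - series(ensemble_a).mean())


def superpose_kabsch(mobile: Frame, reference: Frame, selection: np.ndarray,
                     scoring_selection: Optional[np.ndarray] = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix, translation, rmsd) such that
    ``coords @ R.T + t`` maps mobile coordinates into the reference frame;
    the RMSD is evaluated on ``scoring_selection`` (defaults to the fit
    selection) after applying the fitted transform.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size < 3:
        raise ValueError("need at least 3 atoms to superpose")
    p = mobile.coords[selection]
    q = reference.coords[selection]
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(q - qc, p - pc)
    if np.linalg.matrix_rank(p - pc, tol=1e-8) < 2:
        raise np.linalg.LinAlgError("collinear selection: superposition is degenerate")
    r = rot.as_matrix()
    t = qc - pc @ r.T
    score = selection if scoring_selection is None else np.asarray(scoring_selection, int)
    moved = mobile.coords[score] @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference.coords[score]) ** 2, axis=1))))
    return r, t, rmsd


def mechanism_verdict(delta_alpha_deg: float, delta_z: float,
                      alpha_threshold_deg: float = 5.0,
                      z_threshold: float = 2.0) -> MechanismReport:
    """Classify the motion from the angle change and the vertical offset."""
    if not (np.isfinite(delta_alpha_deg) and np.isfinite(delta_z)):
        raise ValueError("deltas must be finite")
    big_alpha = abs(delta_alpha_deg) >= alpha_threshold_deg
    big_z = abs(delta_z) >= z_threshold
    if big_alpha and big_z:
        verdict = "mixed"
    elif big_alpha:
        verdict = "rocking_bundle"
    elif big_z:
        verdict = "elevator"
    else:
        verdict = "indeterminate"
    return MechanismReport(delta_alpha_deg, delta_z, verdict,
                           alpha_threshold_deg, z_threshold)


def distance_stats(traj: Trajectory | Sequence[Frame], sel_a: np.ndarray,
                   sel_b: np.ndarray, mode: str = "min"
                   ) -> tuple[float, float, np.ndarray]:
    """Per-frame selection-to-selection distance: mean, sample SD and series.

    ``mode='min'`` takes the minimum cross distance per frame (coordination-
    style contact length); ``mode='com'`` the distance between the two
    selection centers of mass.
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("empty selection")
    series = []
    for f in traj:
        pa, pb = f.coords[sel_a], f.coords[sel_b]
        if mode == "min":
            d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)).min()
        elif mode == "com":
            d = np.linalg.norm(pa.mean(0) - pb.mean(0))
        else:
            raise ValueError("mode must be 'min' or 'com'")
        series.append(float(d))
    series = np.array(series)
    sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
    return float(series.mean()), sd, series
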