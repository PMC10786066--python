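"""Mechanism metrics: angles, elevator test, superposition, distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from transmech import geometry as geom
from transmech import synthetic as syn
from transmech.core import (AtomTable, Frame, HelixSegment, LabeledEnsemble,
                            StateLabel, TMTopology)
from transmech.geometry import _vec_angle


@pytest.mark.parametrize("a, b, c, expected", [
    ((0, 0, 10), (0, 0, 0), (10, 0, 0), 90.0),
    ((0, 0, 10), (0, 0, 0), (0, 0, -5), 180.0),
    ((1, 0, 1), (0, 0, 0), (1, 0, 0), 45.0),
])
def test_vertex_angle_constructions(a, b, c, expected):
    a, b, c = (np.array(v, dtype=float) for v in (a, b, c))
    assert _vec_angle(a - b, c - b) == pytest.approx(expected, abs=1e-9)


def test_vertex_angle_degenerate_raises():
    with pytest.raises(ValueError, match="degenerate"):
        _vec_angle(np.zeros(3), np.array([1.0, 0, 0]))


def test_angles_invariant_under_rigid_transform(noiseless_bundle, rng):
    spec, topo, ens = noiseless_bundle
    frame = ens.frames[0]
    rot = Rotation.random(random_state=np.random.RandomState(5))
    t = rng.normal(scale=20.0, size=3)
    moved = Frame(0.0, rot.apply(frame.coords) + t)
    assert geom.bundle_angle(moved, topo) == pytest.approx(
        geom.bundle_angle(frame, topo), abs=1e-9)
    assert geom.kink_angle(moved, topo, "TM10") == pytest.approx(
        geom.kink_angle(frame, topo, "TM10"), abs=1e-9)


def test_kink_angle_straight_and_right_angle():
    # 20-residue helix, backbone = 1 CA per residue for directness
    atoms = AtomTable.from_columns(["CA"] * 21, np.arange(1, 22), ["ALA"] * 21)
    helix = HelixSegment("TM10", (1, 21), extracellular_tip=(20, 21),
                         intracellular_tip=(1, 2), bend_window=(11, 11))
    topo = TMTopology(atoms, [helix], [], [], ["TM10"])
    straight = np.zeros((21, 3))
    straight[:, 2] = np.arange(21) * 1.5
    assert geom.kink_angle(Frame(0, straight), topo, "TM10") == pytest.approx(
        180.0, abs=1e-6)
    bent = straight.copy()
    bent[11:, 2] = straight[10, 2]
    bent[11:, 0] = (np.arange(11, 21) - 10) * 1.5
    assert geom.kink_angle(Frame(0, bent), topo, "TM10") == pytest.approx(
        90.0, abs=1e-6)
    helix_nobend = HelixSegment("TM9", (1, 21), extracellular_tip=(20, 21),
                                intracellular_tip=(1, 2))
    topo2 = TMTopology(atoms, [helix_nobend], [], [], ["TM9"])
    with pytest.raises(ValueError, match="bend_window"):
        geom.kink_angle(Frame(0, straight), topo2, "TM9")


def test_kink_recovery_of_planted_inward_open_angle():
    """The generator's default inward-open helix angle is recovered under noise."""
    spec = syn.BundleSpec(noise_sigma=0.2, seed=13)
    topo, ens = syn.make_two_state_bundle(spec, n_frames_per_state=300)
    thetas = np.array([geom.kink_angle(f, topo, "TM10")
                       for f, lab in zip(ens.frames, ens.labels)
                       if lab is StateLabel.IO])
    sem = thetas.std(ddof=1) / np.sqrt(len(thetas))
    assert abs(thetas.mean() - spec.kink_deg_state_a) < 3 * sem + 0.05


def test_vertical_translation_null_for_pure_rotation(noisy_bundle):
    _, topo, ens = noisy_bundle
    ens_a = ens.subset(StateLabel.IO)
    ens_b = ens.subset(StateLabel.OO)
    dz = geom.vertical_translation(ens_a, ens_b, topo)
    # mobile COM z series SEM bound (coordinate noise / sqrt(atoms*frames))
    assert abs(dz) < 0.05


def test_vertical_translation_detects_planted_shift(noiseless_bundle):
    _, topo, ens = noiseless_bundle
    mobile = np.concatenate([topo.atoms.select(residues=topo.helix(h).residues())
                             for h in topo.mobile_bundle])
    shifted = ens.frames[0].coords.copy()
    shifted[mobile, 2] += 5.0
    ens_a = LabeledEnsemble([ens.frames[0]], [StateLabel.IO])
    ens_b = LabeledEnsemble([Frame(1.0, shifted)], [StateLabel.OO])
    assert geom.vertical_translation(ens_a, ens_b, topo) == pytest.approx(5.0, abs=1e-9)
    with pytest.raises(ValueError, match="empty"):
        geom.vertical_translation(LabeledEnsemble([], []), ens_b, topo)


def test_vertical_translation_matches_brute_force(rng, noiseless_bundle):
    _, topo, ens = noiseless_bundle
    frames_a = [Frame(float(i), ens.frames[0].coords + rng.normal(0, 0.2, ens.frames[0].coords.shape))
                for i in range(4)]
    frames_b = [Frame(float(i), ens.frames[1].coords + rng.normal(0, 0.2, ens.frames[1].coords.shape))
                for i in range(4)]
    ens_a = LabeledEnsemble(frames_a, [StateLabel.IO] * 4)
    ens_b = LabeledEnsemble(frames_b, [StateLabel.OO] * 4)
    dz = geom.vertical_translation(ens_a, ens_b, topo, mode="full")

    mobile = np.concatenate([topo.atoms.select(residues=topo.helix(h).residues(),
                                               backbone_only=True)
                             for h in topo.mobile_bundle])
    static = np.concatenate([topo.atoms.select(residues=topo.helix(h).residues(),
                                               backbone_only=True)
                             for h in topo.static_domain])

    def brute(frames):
        return np.mean([f.coords[mobile, 2].mean() - f.coords[static, 2].mean()
                        for f in frames])

    assert dz == pytest.approx(brute(frames_b) - brute(frames_a), abs=1e-10)


# -- Kabsch superposition ----------------------------------------------------

def _horn_quaternion_rmsd(p, q):
    """Independent optimal-superposition RMSD via Horn's quaternion method."""
    pc = p - p.mean(0)
    qc = q - q.mean(0)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (pc ** 2).sum() + (qc ** 2).sum()
    return float(np.sqrt(max(e0 - 2 * lam, 0.0) / len(p)))


def test_kabsch_identity_and_rigid_invariance(rng):
    coords = rng.normal(size=(20, 3)) * 5
    ref = Frame(0.0, coords)
    sel = np.arange(20)
    _, _, rmsd = geom.superpose_kabsch(ref, ref, sel)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    rot = Rotation.random(random_state=np.random.RandomState(1))
    moved = Frame(0.0, rot.apply(coords) + np.array([3.0, -2.0, 7.0]))
    _, _, rmsd2 = geom.superpose_kabsch(moved, ref, sel)
    assert rmsd2 == pytest.approx(0.0, abs=1e-9)


def test_kabsch_matches_quaternion_oracle(rng):
    p = rng.normal(size=(30, 3)) * 4
    q = p + rng.normal(0, 0.5, size=(30, 3))
    sel = np.arange(30)
    _, _, rmsd = geom.superpose_kabsch(Frame(0, p), Frame(0, q), sel)
    assert rmsd == pytest.approx(_horn_quaternion_rmsd(p, q), abs=1e-8)


def test_kabsch_never_beats_fit_on_scoring_selection(rng):
    p = rng.normal(size=(15, 3)) * 4
    q = p + rng.normal(0, 0.3, size=(15, 3))
    sel = np.arange(15)
    _, _, rmsd_fit = geom.superpose_kabsch(Frame(0, p), Frame(0, q), sel)
    rmsd_identity = float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))
    assert rmsd_fit <= rmsd_identity + 1e-12


def test_kabsch_degenerate_raises():
    line = np.zeros((5, 3))
    line[:, 2] = np.arange(5)
    with pytest.raises(Exception):
        geom.superpose_kabsch(Frame(0, line), Frame(0, line[::-1].copy()),
                              np.arange(5))
    with pytest.raises(ValueError, match="3 atoms"):
        geom.superpose_kabsch(Frame(0, line), Frame(0, line), np.arange(2))


# -- verdicts and distances ---------------------------------------------------

@pytest.mark.parametrize("d_alpha, dz, expected", [
    (14.0, 0.3, "rocking_bundle"),
    (0.0, 6.0, "elevator"),
    (6.0, 3.0, "mixed"),
    (1.0, 0.5, "indeterminate"),
])
def test_mechanism_verdict_rules(d_alpha, dz, expected):
    assert geom.mechanism_verdict(d_alpha, dz).verdict == expected


def test_mechanism_verdict_rejects_nonfinite():
    with pytest.raises(ValueError):
        geom.mechanism_verdict(float("nan"), 0.0)


def test_distance_stats_hand_values():
    c0 = np.array([[0.0, 0, 0], [0.0, 0, 3]])
    c1 = np.array([[0.0, 0, 0], [0.0, 0, 3]])
    frames = [Frame(0, c0), Frame(1, c1)]
    mean, sd, series = geom.distance_stats(frames, [0], [1])
    assert (mean, sd) == (3.0, 0.0)
    frames2 = [Frame(0, np.array([[0.0, 0, 0], [2.0, 0, 0]])),
               Frame(1, np.array([[0.0, 0, 0], [4.0, 0, 0]]))]
    mean2, sd2, _ = geom.distance_stats(frames2, [0], [1])
    assert mean2 == pytest.approx(3.0)
    assert sd2 == pytest.approx(np.sqrt(2))  # sample SD convention


def test_distance_stats_matches_brute_force(rng):
    frames = [Frame(float(i), rng.normal(size=(8, 3)) * 3) for i in range(5)]
    sel_a, sel_b = np.array([0, 1, 2]), np.array([5, 6])
    mean, sd, series = geom.distance_stats(frames, sel_a, sel_b, mode="min")
    brute = [min(np.linalg.norm(f.coords[i] - f.coords[j])
                 for i in sel_a for j in sel_b) for f in frames]
    np.testing.assert_allclose(series, brute, atol=1e-12)
    assert mean == pytest.approx(np.mean(brute), abs=1e-12)
    assert sd == pytest.approx(np.std(brute, ddof=1), abs=1e-12)
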