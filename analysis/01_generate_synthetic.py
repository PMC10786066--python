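#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Writes the two-state helix bundle (PDB topology, multi-frame XYZ, helix
annotations, state labels), a state-transition trajectory, the planted
90-pair distance ensemble, and a water slab with 10 scripted permeation
events, each with its ground-truth sidecar, under results/data/.
"""

import numpy as np

from transmech import synthetic as syn
from transmech.core import Trajectory, write_helix_yaml, write_pdb, write_xyz
from _util import DATA, tsv

SEED = 1


def main():
    DATA.mkdir(parents=True, exist_ok=True)

    # Two-state bundle: 500 frames per state, 0.3 A coordinate noise,
    # planted 14 deg rocking rotation and 151.2 -> 169.2 deg kink change.
    spec = syn.BundleSpec(noise_sigma=0.3, seed=SEED)
    topo, ens = syn.make_two_state_bundle(spec, n_frames_per_state=500)
    write_pdb(DATA / "bundle_stateA.pdb", topo.atoms, ens.frames[0])
    write_helix_yaml(DATA / "helices.yaml", topo)
    write_xyz(DATA / "bundle_two_state.xyz", topo.atoms,
              Trajectory(ens.frames, 1.0))
    tsv(DATA / "bundle_labels.tsv", ["frame", "label"],
        [(i, lab.value) for i, lab in enumerate(ens.labels)])

    # One interpolated transition (the synthetic analogue of a biased
    # IO -> OO crossing), noise-free for clean angle traces.
    tspec = syn.BundleSpec(noise_sigma=0.0, seed=SEED)
    _, transition = syn.make_transition_trajectory(tspec, n_frames=101)
    write_xyz(DATA / "transition.xyz", topo.atoms, transition)

    # Planted 90-pair distance ensemble for CV design.
    fspec = syn.FeatureEnsembleSpec(seed=SEED)
    fa, fb, truth = syn.make_feature_ensemble(fspec)
    np.savetxt(DATA / "features_stateA.tsv", fa, fmt="%.6f", delimiter="\t",
               header="planted 90-pair distances, inward-open state (A)")
    np.savetxt(DATA / "features_stateB.tsv", fb, fmt="%.6f", delimiter="\t",
               header="planted 90-pair distances, outward-open state (A)")
    tsv(DATA / "features_truth.tsv", ["informative_pair"], [(int(i),) for i in truth])

    # Water slab: 400 waters, 10 scripted permeations among random walkers.
    rng = np.random.default_rng(SEED)
    events = []
    for k in range(10):
        start = int(rng.integers(10, 1500))
        events.append(syn.ScriptedEvent(
            water_id=k, direction="efflux" if k % 2 == 0 else "influx",
            start_frame=start, end_frame=start + int(rng.integers(150, 350))))
    wspec = syn.WaterSlabSpec(n_waters=400, scripted_events=events, seed=SEED)
    traj, atoms, truth_events = syn.make_water_slab(wspec, 2000)
    write_xyz(DATA / "water_slab.xyz", atoms, traj)
    tsv(DATA / "water_truth.tsv",
        ["water_id", "direction", "t_start_ns", "t_end_ns"],
        [(e.water_id, e.direction, e.t_start, e.t_end) for e in truth_events])

    print(f"wrote bundle ({len(topo.atoms)} atoms, {len(ens)} frames), "
          f"transition (101 frames), features (90 pairs x 2x5000 frames), "
          f"water slab (400 waters, 2000 frames, {len(truth_events)} planted "
          f"events) -> {DATA}")


if __name__ == "__main__":
    main()
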