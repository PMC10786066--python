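import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Two-state 12-helix bundle with exact planted rotation, no noise."""
    from transmech import synthetic as syn
    spec = syn.BundleSpec(noise_sigma=0.0, seed=7)
    topo, ens = syn.make_two_state_bundle(spec, n_frames_per_state=1)
    return spec, topo, ens


@pytest.fixture(scope="session")
def noisy_bundle():
    """500 frames/state with 0.3 A coordinate noise (statistical recovery)."""
    from transmech import synthetic as syn
    spec = syn.BundleSpec(noise_sigma=0.3, seed=11)
    topo, ens = syn.make_two_state_bundle(spec, n_frames_per_state=500)
    return spec, topo, ens
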