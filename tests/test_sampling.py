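"""Switching-function CVs, the OPES-Explore engine and FES reweighting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from transmech import sampling as smp
from transmech import synthetic as syn
from transmech.core import Frame


# -- rational switching function ---------------------------------------------

def test_switch_at_d0_is_one():
    p = smp.SwitchingParams(r0=8.0, d0=0.0, n=2, m=8)
    assert smp.rational_switch(0.0, p) == pytest.approx(1.0)
    p2 = smp.SwitchingParams(r0=2.0, d0=1.5, n=2, m=6)
    assert smp.rational_switch(1.5, p2) == pytest.approx(1.0)
    assert smp.rational_switch(0.5, p2) == pytest.approx(1.0)  # below d0 clamps


def test_switch_removable_singularity():
    p = smp.SwitchingParams(r0=8.0, d0=0.0, n=2, m=8)
    assert smp.rational_switch(8.0, p) == pytest.approx(0.25, abs=1e-12)
    p2 = smp.SwitchingParams(r0=3.0, d0=1.0, n=4, m=10)
    assert smp.rational_switch(4.0, p2) == pytest.approx(0.4, abs=1e-12)


def test_switch_direct_evaluation():
    p = smp.SwitchingParams(r0=8.0, d0=0.0, n=2, m=8)
    # x = 2: (1-4)/(1-256) = 3/255
    assert smp.rational_switch(16.0, p) == pytest.approx(3.0 / 255.0, abs=1e-12)


def test_ion_site_parameters():
    assert smp.ION_SITE_SWITCH.r0 == 2.35
    assert (smp.ION_SITE_SWITCH.n, smp.ION_SITE_SWITCH.m) == (2, 8)


@given(st.floats(0.5, 20.0), st.floats(0.0, 5.0),
       st.sampled_from([2, 4, 6]), st.sampled_from([8, 10, 12]),
       st.integers(0, 10 ** 6))
def test_switch_monotone_non_increasing(r0, d0, n, m, seed):
    p = smp.SwitchingParams(r0=r0, d0=d0, n=n, m=m)
    rng = np.random.default_rng(seed)
    r = np.sort(rng.uniform(d0, d0 + 6 * r0, size=50))
    s = smp.rational_switch(r, p)
    assert np.all(np.diff(s) <= 1e-12)
    assert np.all((s >= -1e-12) & (s <= 1.0 + 1e-12))


# -- coordination CV ----------------------------------------------------------

def test_coordination_trivial_values():
    p = smp.SwitchingParams()
    coords = np.zeros((10, 3))
    spec = smp.CoordinationCVSpec(center=np.zeros(3), partners=np.arange(10),
                                  params=p)
    assert smp.coordination_cv(Frame(0, coords), spec) == pytest.approx(10.0)
    far = np.full((4, 3), 1e4)
    spec2 = smp.CoordinationCVSpec(center=np.zeros(3), partners=np.arange(4),
                                   params=p)
    assert smp.coordination_cv(Frame(0, far), spec2) == pytest.approx(0.0, abs=1e-12)


def test_coordination_matches_brute_force_and_rigid_invariance(rng):
    p = smp.SwitchingParams(r0=4.0)
    coords = rng.uniform(-10, 10, (30, 3))
    center = np.array([1.0, -2.0, 3.0])
    spec = smp.CoordinationCVSpec(center=center, partners=np.arange(30), params=p)
    cv = smp.coordination_cv(Frame(0, coords), spec)
    brute = sum(smp.rational_switch(float(np.linalg.norm(c - center)), p)
                for c in coords)
    assert cv == pytest.approx(brute, abs=1e-12)
    rot = Rotation.random(random_state=np.random.RandomState(2))
    t = np.array([5.0, 1.0, -9.0])
    spec_r = smp.CoordinationCVSpec(center=rot.apply(center) + t,
                                    partners=np.arange(30), params=p)
    cv_r = smp.coordination_cv(Frame(0, rot.apply(coords) + t), spec_r)
    assert cv_r == pytest.approx(cv, abs=1e-9)


# -- OPES engine --------------------------------------------------------------

def test_opes_kernel_count_and_empty_bias():
    cfg = smp.OPESConfig(barrier=10.0, stride=100)
    state = smp.BiasState(cfg, ndim=1)
    assert smp.opes_bias(state, 0.3) == 0.0
    for k in range(7):
        smp.opes_update(state, [0.1 * k])
    assert state.n_kernels == 7


def test_opes_single_kernel_hand_evaluation():
    cfg = smp.OPESConfig(barrier=10.0, stride=100, sigma_initial=(0.2,),
                         sigma_min=(0.1,), adaptive=False)
    state = smp.BiasState(cfg, ndim=1)
    smp.opes_update(state, [0.5])
    gamma = cfg.gamma
    kT = cfg.kT
    eps = np.exp(-cfg.barrier / ((gamma - 1) * kT))
    h = 1.0 / (np.sqrt(2 * np.pi) * 0.2)
    # at the kernel center: p = h, Z = mean center density = h
    expected = min((gamma - 1) * kT * (np.log(1.0 + eps) - np.log(eps)), cfg.barrier)
    assert smp.opes_bias(state, 0.5) == pytest.approx(expected, abs=1e-10)
    off = 0.5 + 0.3
    p_off = h * np.exp(-0.5 * (0.3 / 0.2) ** 2)
    expected_off = min((gamma - 1) * kT * (np.log(p_off / h + eps) - np.log(eps)),
                       cfg.barrier)
    assert smp.opes_bias(state, off) == pytest.approx(expected_off, abs=1e-10)


def test_opes_bias_translation_equivariance(rng):
    cfg = smp.OPESConfig(barrier=8.0, stride=50, sigma_initial=(0.3,),
                         sigma_min=(0.1,), adaptive=False)
    state = smp.BiasState(cfg, ndim=1)
    pts = rng.normal(size=12)
    for x in pts:
        smp.opes_update(state, [x])
    shifted = smp.BiasState(cfg, ndim=1)
    for x in pts + 2.5:
        smp.opes_update(shifted, [x])
    grid = np.linspace(-2, 2, 31)
    np.testing.assert_allclose(smp.opes_bias(shifted, (grid + 2.5)[:, None]),
                               smp.opes_bias(state, grid[:, None]), atol=1e-9)


def test_opes_bias_bounded_by_barrier(rng):
    cfg = smp.OPESConfig(barrier=6.0, stride=10, sigma_initial=(0.1,),
                         sigma_min=(0.05,))
    state = smp.BiasState(cfg, ndim=1)
    for x in rng.normal(0, 0.2, size=200):
        smp.opes_update(state, [x])
    grid = np.linspace(-3, 3, 301)[:, None]
    v = state.bias(grid)
    assert np.all(v >= 0.0)
    assert np.all(v <= cfg.barrier + 1e-12)


def test_opes_rejects_nonfinite_point():
    state = smp.BiasState(smp.OPESConfig(), ndim=1)
    with pytest.raises(RuntimeError):
        smp.opes_update(state, [np.nan])


def test_opes_flattens_harmonic_well():
    """Biased sampling approaches the flattened target: the sampled marginal
    over the well broadens quarter by quarter (decreasing KL to uniform)."""
    pot = syn.PotentialSpec(form="harmonic", k=8.0)
    cfg = smp.OPESConfig(barrier=8.0, stride=200, sigma_initial=(0.15,),
                         sigma_min=(0.05,))
    run = smp.run_opes_langevin(pot, cfg, n_steps=300_000, dt=0.002, seed=5,
                                x0=0.0, record_stride=5)
    edges = np.linspace(-1.2, 1.2, 25)
    quarters = np.array_split(run.cv, 4)

    def kl_to_uniform(x):
        h, _ = np.histogram(x, bins=edges)
        p = h / h.sum()
        q = np.full_like(p, 1 / len(p), dtype=float)
        mask = p > 0
        return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))

    kls = [kl_to_uniform(q) for q in quarters]
    assert kls[-1] < kls[0]


# -- reweighting --------------------------------------------------------------

def test_reweight_zero_bias_equals_boltzmann_inversion(rng):
    kT = 0.6
    samples = rng.normal(0.0, 0.5, size=20000)
    grid = np.linspace(-1.5, 1.5, 61)
    f = smp.reweight_fes(samples, np.zeros_like(samples), kT, grid)
    half = 0.5 * (grid[1] - grid[0])
    hist, _ = np.histogram(samples, bins=np.concatenate([grid - half,
                                                         [grid[-1] + half]]))
    with np.errstate(divide="ignore"):
        f_ref = -kT * np.log(hist.astype(float))
    f_ref -= f_ref[np.isfinite(f_ref)].min()
    np.testing.assert_allclose(f[np.isfinite(f_ref)], f_ref[np.isfinite(f_ref)],
                               atol=1e-9)


def test_reweight_gaussian_samples_quadratic_fes(rng):
    kT = 0.6163
    sigma = 0.4
    samples = rng.normal(0.0, sigma, size=200_000)
    grid = np.linspace(-0.8, 0.8, 33)
    f = smp.reweight_fes(samples, np.zeros_like(samples), kT, grid)
    expected = 0.5 * kT * grid ** 2 / sigma ** 2
    expected -= expected.min()
    np.testing.assert_allclose(f, expected, atol=0.05)


def test_reweight_requires_aligned_nonempty_series():
    with pytest.raises(ValueError):
        smp.reweight_fes(np.zeros(0), np.zeros(0), 0.6, np.linspace(-1, 1, 11))
    with pytest.raises(ValueError):
        smp.reweight_fes(np.zeros(5), np.zeros(4), 0.6, np.linspace(-1, 1, 11))


def test_bidimensional_opes_separates_wells():
    """2-D biased run (double well in x, harmonic in y): the reweighted 2-D
    FES shows the two x-wells with the y marginal centered at 0."""
    from transmech import fes as fesmod
    pot = syn.PotentialSpec(form="double_well_2d", h=4.0, ky=2.0)
    cfg = smp.OPESConfig(barrier=8.0, stride=200)  # gentle cap for the 4 kcal/mol well
    run = smp.run_opes_langevin(pot, cfg, n_steps=400_000, dt=0.002, seed=11,
                                record_stride=5)
    assert run.cv.shape[1] == 2
    assert run.state.n_kernels == 400_000 // 200
    gx = np.linspace(-1.5, 1.5, 61)
    gy = np.linspace(-1.2, 1.2, 25)
    f = smp.reweight_fes(run.cv, run.bias, pot.kT, (gx, gy),
                         kernel_width=0.08, burn_in_fraction=0.25)
    # smooth-kernel FES is finite everywhere; keep basins near the floor
    basins = fesmod.find_basins(fesmod.FESGrid((gx, gy), f), min_depth=1.5,
                                energy_window=3.0)
    assert len(basins) == 2
    xs = sorted(gx[b.location[0]] for b in basins.basins)
    assert xs[0] == pytest.approx(-1.0, abs=0.2)
    assert xs[1] == pytest.approx(1.0, abs=0.2)
    for b in basins.basins:
        assert gy[b.location[1]] == pytest.approx(0.0, abs=0.3)


def test_opes_recovers_double_well_barrier_short_run():
    """A moderate biased run already recovers the planted barrier to ~10%."""
    pot = syn.PotentialSpec(form="double_well_1d", h=5.0)
    cfg = smp.OPESConfig()
    run = smp.run_opes_langevin(pot, cfg, n_steps=400_000, dt=0.002, seed=7,
                                record_stride=10)
    grid = np.linspace(-1.4, 1.4, 141)
    f = smp.reweight_fes(run.cv, run.bias, pot.kT, grid, burn_in_fraction=0.25)
    barrier = f[np.argmin(np.abs(grid))] - 0.5 * (
        f[np.argmin(np.abs(grid + 1))] + f[np.argmin(np.abs(grid - 1))])
    assert barrier == pytest.approx(5.0, abs=0.6)
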