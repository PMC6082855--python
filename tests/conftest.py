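"""Shared reduced-scale simulation ensembles.

Session-scoped fixtures so the expensive collapse/production runs are built
once and shared across the simulator, observable and acceptance tests.
Problem sizes (N = 320-1000, few seeds, short productions) keep the whole
suite desk-scale while preserving collapsed-globule physics.
"""

import numpy as np
import pytest

import ccmpoly as cp
from ccmpoly.core import EnergyModel, OverstretchedBondError

N_SHARED = 320


def retry_overstretch(fn, seed, n_tries=3):
    """Re-run a stochastic integration with a fresh noise stream on the rare
    occasions a chain bond transiently leaves the FENE domain."""
    for k in range(n_tries):
        try:
            return fn(seed + 50_000 * k)
        except OverstretchedBondError:
            continue
    raise RuntimeError("integration failed repeatedly")


@pytest.fixture(scope="session")
def shared_system():
    """Block-copolymer chain (24% active) with a few loops, standard model defaults."""
    ann = cp.synth_annotation(N_SHARED, mean_block_len=20, fraction_a=0.24, seed=7)
    loops = cp.synth_loops(N_SHARED, 3, 40, seed=8)
    return ann, loops


def collapse_start(model, seed, n_steps=80_000):
    """Fast low-friction Langevin collapse from an extended conformation."""
    def run(s):
        pos0 = cp.init_extended(model, seed=s)
        col = cp.run_langevin(pos0, model, n_steps=n_steps, dt=0.01,
                              friction_low=0.1, seed=s, save_every=n_steps)
        return col.frames[-1]

    return retry_overstretch(run, seed)


def _bd_ensemble(ann, loops, n, epsilon, seeds, n_steps):
    params = cp.CCMParameters(n_beads=n, epsilon=epsilon)
    model = EnergyModel(params, ann, loops)
    trajs = []
    for s in seeds:
        start = collapse_start(model, s, n_steps=80_000 if n <= 400 else 120_000)
        trajs.append(retry_overstretch(
            lambda ss: cp.run_brownian(start, model, n_steps=n_steps, dt=1e-4,
                                       seed=ss + 1000, save_every=50), s))
    return params, model, trajs


@pytest.fixture(scope="session")
def glass_bd_ensemble(shared_system):
    """Collapsed epsilon = 2.4 chains with overdamped production (15 tau)."""
    ann, loops = shared_system
    return _bd_ensemble(ann, loops, N_SHARED, 2.4, [1, 2, 3], 150_000)


@pytest.fixture(scope="session")
def liquid_bd_ensemble(shared_system):
    """Matched epsilon = 1.0 control runs (same seeds and chain)."""
    ann, loops = shared_system
    return _bd_ensemble(ann, loops, N_SHARED, 1.0, [1, 2, 3], 150_000)


def _relax_ensemble(ann, loops, epsilon, seeds):
    params = cp.CCMParameters(n_beads=N_SHARED, epsilon=epsilon)
    model = EnergyModel(params, ann, loops)
    trajs = []
    for s in seeds:
        start = collapse_start(model, s)
        trajs.append(retry_overstretch(
            lambda ss: cp.run_langevin(start, model, n_steps=60_000, dt=0.01,
                                       friction_low=1.0, seed=ss + 2000,
                                       save_every=150), s))
    return params, model, trajs


@pytest.fixture(scope="session")
def glass_relax_ensemble(shared_system):
    """Five independent 600-tau unit-friction runs at epsilon = 2.4 (chi4)."""
    ann, loops = shared_system
    return _relax_ensemble(ann, loops, 2.4, [1, 2, 3, 4, 5])


@pytest.fixture(scope="session")
def liquid_relax_ensemble(shared_system):
    ann, loops = shared_system
    return _relax_ensemble(ann, loops, 1.0, [1, 2, 3, 4, 5])


@pytest.fixture(scope="session")
def glass_sampling_traj(shared_system):
    """1500-tau Langevin sampling of a collapsed 2.4 globule.

    Static observables (contact maps, distance maps, P(s), lambda) are
    measured here: low/unit-friction Langevin covers conformational space
    far faster than Brownian dynamics at equal wall time.
    """
    ann, loops = shared_system
    params = cp.CCMParameters(n_beads=N_SHARED, epsilon=2.4)
    model = EnergyModel(params, ann, loops)
    start = collapse_start(model, 11)
    traj = retry_overstretch(
        lambda s: cp.run_langevin(start, model, n_steps=150_000, dt=0.01,
                                  friction_low=1.0, seed=s, save_every=300),
        1011)
    return params, ann, loops, traj


@pytest.fixture(scope="session")
def msd_ensemble_n500():
    """Collapsed N = 500 chains with overdamped production for the global MSD
    exponent (stronger caging than the shared N = 320 system)."""
    n = 500
    ann = cp.synth_annotation(n, 20, 0.24, seed=21)
    loops = cp.synth_loops(n, 5, 40, seed=22)
    params = cp.CCMParameters(n_beads=n, epsilon=2.4)
    model = EnergyModel(params, ann, loops)
    trajs = []
    for s in (1, 2, 3):
        start = collapse_start(model, s, n_steps=100_000)
        trajs.append(retry_overstretch(
            lambda ss: cp.run_brownian(start, model, n_steps=100_000, dt=1e-4,
                                       seed=ss + 3000, save_every=50), s))
    return params, model, trajs


@pytest.fixture(scope="session")
def droplet_collapses():
    """Unit-friction (diffusive) collapses of N = 500 chains with frames
    saved through the coalescence stage."""
    n = 500
    ann = cp.synth_annotation(n, 20, 0.24, seed=21)
    loops = cp.synth_loops(n, 5, 40, seed=22)
    params = cp.CCMParameters(n_beads=n, epsilon=2.4)
    model = EnergyModel(params, ann, loops)
    cols = []
    for s in (1, 2, 3):
        def run(ss):
            pos0 = cp.init_extended(model, seed=ss)
            return cp.run_langevin(pos0, model, n_steps=150_000, dt=0.01,
                                   friction_low=1.0, seed=ss, save_every=1000)
        cols.append(retry_overstretch(run, s + 40))
    return params, cols


def collapse_to_globule(model, seed, rg_target, chunk=100_000, max_chunks=5):
    """Collapse until Rg plateaus at the compact-globule value."""
    from ccmpoly.geometry import radius_of_gyration

    pos = cp.init_extended(model, seed=seed)
    for k in range(max_chunks):
        col = retry_overstretch(
            lambda s: cp.run_langevin(pos, model, n_steps=chunk, dt=0.01,
                                      friction_low=0.1, seed=s,
                                      save_every=chunk), seed + 7 * k + 1)
        pos = col.frames[-1]
        if radius_of_gyration(col)[-1] < rg_target:
            break
    return pos


@pytest.fixture(scope="session")
def large_sampling_traj():
    """N = 800 collapsed globule with Langevin sampling: the largest chain
    the suite affords, for the two-regime contact-probability analysis."""
    n = 800
    ann = cp.synth_annotation(n, 20, 0.24, seed=31)
    loops = cp.synth_loops(n, 8, 40, seed=32)
    params = cp.CCMParameters(n_beads=n, epsilon=2.4)
    model = EnergyModel(params, ann, loops)
    # compact-globule Rg at melt density ~1/sigma^3 is ~4.5 sigma for N=800
    start = collapse_to_globule(model, 33, rg_target=5.5)
    traj = retry_overstretch(
        lambda s: cp.run_langevin(start, model, n_steps=80_000, dt=0.01,
                                  friction_low=1.0, seed=s, save_every=300),
        1033)
    return params, traj


@pytest.fixture(scope="session")
def homopolymer_sampling_traj(shared_system):
    """Pseudo-homopolymer control: eps_AB = eps (eps_ratio = 1), same chain."""
    ann, loops = shared_system
    params = cp.CCMParameters(n_beads=N_SHARED, epsilon=2.4, eps_ratio=1.0)
    model = EnergyModel(params, ann, loops)
    start = collapse_start(model, 12)
    traj = retry_overstretch(
        lambda s: cp.run_langevin(start, model, n_steps=50_000, dt=0.01,
                                  friction_low=1.0, seed=s, save_every=300),
        1012)
    return params, ann, traj
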