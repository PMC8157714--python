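"""Shared fixtures: expensive synthetic trajectories are session-scoped
so the unit and acceptance suites can reuse them."""

import numpy as np
import pytest

from cavitydiff import synthetic_data as sd


@pytest.fixture(scope="session")
def two_state_traj():
    """Exact two-state jump process, k12=1, k21=4 ns^-1 (truth in meta)."""
    traj, states = sd.gen_two_state_jump(
        k12=1.0, k21=4.0, emission_sd=0.08, dt=1.0, n_steps=50_000, seed=1
    )
    return traj, states


@pytest.fixture(scope="session")
def hopping_traj():
    """Deep two-well Langevin trajectory with clean cavity hopping.

    Wells 12 kBT deep, width 0.42 nm, centers 1.28 nm apart along x in a
    2.56 nm periodic box: the inter-well saddle sits ~4.5 kBT above the
    well bottoms while the flat background lies ~12 kBT up, so transport
    is hop-dominated (hop length 1.28 nm both ways around the ring).
    """
    traj = sd.gen_langevin_trajectory(
        wells=[
            ((0.64, 1.28, 1.28), 12.0, 0.42),
            ((1.92, 1.28, 1.28), 12.0, 0.42),
        ],
        box=(2.56, 2.56, 2.56),
        friction=10.0,
        dt=0.01,
        n_steps=10_000_000,
        sample_stride=10,
        seed=11,
    )
    traj.meta["hop_length_nm"] = 1.28
    return traj


@pytest.fixture(scope="session")
def boltzmann_traj():
    """Long single-well Langevin run for Boltzmann-consistency checks."""
    return sd.gen_langevin_trajectory(
        wells=[((2.0, 2.0, 2.0), 4.0, 0.35)],
        box=(4.0, 4.0, 4.0),
        friction=10.0,
        dt=0.01,
        n_steps=10_000_000,
        sample_stride=10,
        seed=3,
    )


@pytest.fixture(scope="session")
def brownian_traj():
    """Free Brownian motion, D = 1e-9 m^2/s (1e-3 nm^2/ps), unwrapped."""
    rng = np.random.default_rng(0)
    d0 = 1e-3
    dt = 1.0
    n = 200_000
    x = np.cumsum(np.sqrt(2 * d0 * dt) * rng.standard_normal((n, 3)), axis=0) + 500.0
    from cavitydiff.trajectory import Trajectory

    return Trajectory(
        times=np.arange(n) * dt,
        positions=np.mod(x, 1000.0),
        unwrapped=x,
        box=np.array([1000.0, 1000.0, 1000.0]),
        meta={"d_true_m2s": 1e-9},
    )
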