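"""Shared fixtures: all test systems are generated programmatically."""

import numpy as np
import pytest

import crowdbd as c


class ZeroNoiseRng:
    """RNG stub whose Gaussian draws are all zero (drift-only stepping)."""

    def normal(self, size=None):
        return np.zeros(size)


@pytest.fixture(scope="session")
def free_sphere_trajectory():
    """64 effectively non-interacting spheres (r = 5 Å) in a huge box,
    10 ns of BD recorded every 100 ps — a normal-diffusion reference."""
    state = c.make_sphere_fluid(64, 5.0, 5000.0, seed=11)
    traj, _, _ = c.run_simulation(state, 4000, record_every=40)
    return traj, state.templates[0]


@pytest.fixture(scope="session")
def free_rotor_trajectory():
    """400 isolated spheres; rotational sampling every 10 ps for 1 ns."""
    state = c.make_sphere_fluid(400, 5.0, 50000.0, seed=13,
                                min_surface_sep=0.0)
    traj, _, _ = c.run_simulation(state, 400, record_every=4)
    return traj, state.templates[0]


@pytest.fixture(scope="session")
def dense_sphere_run():
    """100 hard spheres at packing fraction ~0.10: (trajectory, final
    state, template)."""
    n, r = 100, 10.0
    L = (n * 4 / 3 * np.pi * r ** 3 / 0.10) ** (1 / 3)
    state = c.make_sphere_fluid(n, r, L, seed=17)
    traj, log, fin = c.run_simulation(state, 1200, record_every=40)
    return traj, log, fin


def equilibrated_hs_snapshots(y, n=200, r=10.0, n_snapshots=3,
                              n_steps=2000, seed0=100):
    """Independent equilibrated hard-sphere fluid snapshots at packing y."""
    L = (n * 4 / 3 * np.pi * r ** 3 / y) ** (1 / 3)
    out = []
    for s in range(n_snapshots):
        st = c.make_sphere_fluid(n, r, L, seed=seed0 + s)
        _, _, fin = c.run_simulation(st, n_steps, record_every=n_steps)
        out.append(fin)
    return out
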