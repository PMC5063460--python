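"""Shared fixtures: small synthetic trajectories and profile fixtures.

Heavier simulation fixtures are module-scoped inside the test modules
that need them; here live only the cheap, widely shared ones.
"""
from __future__ import annotations

import numpy as np
import pytest

import tetherlytics as tl


@pytest.fixture(scope="session")
def slab() -> tl.SlabDomain:
    return tl.SlabDomain(z_b=0.0, z_t=5.0, L_x=10.8, L_y=10.8)


@pytest.fixture(scope="session")
def flat_traj(slab) -> tl.Trajectory:
    """Flat landscape, constant D = 1 nm^2/ns in all directions."""
    spec = tl.LangevinSpec(
        domain=slab, free_energy=None, diffusion_z=1.0, diffusion_xy=1.0,
        temperature=320.0, n_particles=200, dt=1e-3, n_steps=20_000, seed=101,
    )
    return tl.simulate_overdamped(spec)


@pytest.fixture(scope="session")
def harmonic_traj() -> tl.Trajectory:
    """Boltzmann sampling of a harmonic well, k = 10 kJ/mol/nm^2 at 320 K."""
    dom = tl.SlabDomain(z_b=-2.5, z_t=2.5, L_x=10.0, L_y=10.0)
    spec = tl.LangevinSpec(
        domain=dom, free_energy=lambda z: 0.5 * 10.0 * np.asarray(z) ** 2,
        diffusion_z=1.0, temperature=320.0, n_particles=100, dt=1e-3,
        n_steps=10_000, seed=2, init="boltzmann",
    )
    return tl.simulate_overdamped(spec)


def make_pmf(z, G, temperature=320.0):
    """PMF container from explicit arrays, gauge-shifted to min 0."""
    G = np.asarray(G, dtype=float)
    return tl.PMF(bin_centers=np.asarray(z, dtype=float), G=G - np.nanmin(G),
                  support=np.ones_like(G), temperature=temperature)


@pytest.fixture()
def double_well_pmf():
    """Symmetric double well: minima at +-1.82 nm, interior barrier at 0."""
    z = np.linspace(-4.5, 4.5, 181)
    z0 = 1.82
    G = 89.0 * ((z ** 2 - z0 ** 2) ** 2) / z0 ** 4
    G = np.minimum(G, 120.0)  # clip the outer walls to a solvated plateau
    return make_pmf(z, G)
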