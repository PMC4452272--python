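"""Shared fixtures: toy dimers, rings and subsystems built at test time."""

import numpy as np
import pytest

from mtring import (
    LatticeSpec,
    ToyDimerSpec,
    build_ring,
    enumerate_subsystems,
    make_toy_dimer,
)


@pytest.fixture(scope="session")
def toy_spec():
    return ToyDimerSpec(seed=1)


@pytest.fixture(scope="session")
def toy_dimer(toy_spec):
    atoms, _ = make_toy_dimer(toy_spec)
    return atoms


@pytest.fixture(scope="session")
def toy_params(toy_spec):
    _, params = make_toy_dimer(toy_spec)
    return params


@pytest.fixture(scope="session")
def small_spec():
    # ring radius chosen so toy dimers form real lateral contacts
    return LatticeSpec(ring_radius=36.0)


@pytest.fixture(scope="session")
def toy_ring(small_spec, toy_dimer):
    return build_ring(small_spec, toy_dimer)


@pytest.fixture(scope="session")
def toy_subsystems(toy_ring):
    return enumerate_subsystems(toy_ring)


def brute_min_dist(a, b):
    d = np.sqrt(((a.coords[:, None, :] - b.coords[None, :, :]) ** 2).sum(-1))
    return d.min()
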