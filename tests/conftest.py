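"""Shared fixtures: scaled-down networks and short reusable simulations."""

import numpy as np
import pytest
import scipy.sparse as sp

from rewirenet import (SCALED_DOWN, DirectedNetwork, RewireConfig, SimConfig,
                       build_random_fixed_indegree, build_ring_lattice,
                       rewire_lattice, simulate)
from rewirenet.dynamics import RecordConfig, SCALED_EXT_RATE


@pytest.fixture(scope="session")
def scaled_random():
    return build_random_fixed_indegree(SCALED_DOWN)


@pytest.fixture(scope="session")
def scaled_lattice():
    return build_ring_lattice(SCALED_DOWN)


@pytest.fixture(scope="session")
def scaled_rewired(scaled_lattice):
    return rewire_lattice(scaled_lattice,
                          RewireConfig(p2=0.075, p3=0.05, seed=3))


@pytest.fixture(scope="session")
def short_run(scaled_random):
    """2-s scaled random-network run with all traces recorded."""
    sc = SimConfig(duration=2000.0, ext_rate=SCALED_EXT_RATE, seed=11,
                   record=RecordConfig(v_traces=True, conductance_traces=True))
    return simulate(scaled_random, sc=sc)


def single_neuron_net(is_exc=True):
    """One isolated neuron as a degenerate network."""
    ei = np.array([0 if is_exc else 1], dtype=np.int8)
    return DirectedNetwork(sp.csr_matrix((1, 1), dtype=bool), ei,
                           provenance={"constant_indegree": False})


def two_neuron_net(src_exc=True, tgt_exc=True):
    """Two neurons with a single edge 0 -> 1."""
    adj = sp.csr_matrix(np.array([[False, True], [False, False]]))
    ei = np.array([0 if src_exc else 1, 0 if tgt_exc else 1], dtype=np.int8)
    return DirectedNetwork(adj, ei, provenance={"constant_indegree": False})
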