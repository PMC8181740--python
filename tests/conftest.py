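import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # for the oracles module

from counterstream import BinaryNetwork, SyntheticSpec, WeightedConnectome, generate


def binary_from_edges(nodes, edges):
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in edges:
        A[idx[u], idx[v]] = True
    return BinaryNetwork(list(nodes), A)


def weighted_from_edges(nodes, edges):
    """edges: dict (u, v) -> (fln, sln, dist)."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    fln = np.full((n, n), np.nan)
    sln = np.full((n, n), np.nan)
    dist = np.full((n, n), np.nan)
    for (u, v), (f, s, d) in edges.items():
        fln[idx[u], idx[v]] = f
        sln[idx[u], idx[v]] = s
        dist[idx[u], idx[v]] = d
    return WeightedConnectome(list(nodes), fln, sln, dist)


@pytest.fixture
def funnel_net():
    """{a->c, b->c, c->d}: the canonical convergent-edge example."""
    return binary_from_edges("abcd", [("a", "c"), ("b", "c"), ("c", "d")])


@pytest.fixture
def diamond_net():
    """a->b->d and a->c->d: a tied-shortest-path pair."""
    return binary_from_edges("abcd", [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")])


@pytest.fixture(scope="session")
def synthetic_connectome():
    """One deterministic mid-size synthetic weighted connectome + truth."""
    net, levels = generate(SyntheticSpec(n_areas=16, seed=7))
    return net, levels


@pytest.fixture(scope="session")
def hierarchical_8net():
    """Small, strongly hierarchical connectome for dynamics/GC tests."""
    spec = SyntheticSpec(
        n_areas=8,
        target_density=0.7,
        sln_slope=3.0,
        bb_dispersion=1e-3,
        hierarchy_levels=np.linspace(0.0, 2.5, 8),
        seed=21,
    )
    net, levels = generate(spec)
    return net, levels
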