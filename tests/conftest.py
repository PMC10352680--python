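"""Shared fixtures: small named graphs, random-graph factories, configs."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from keygenet import SimulationConfig

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.complete_graph(3)


@pytest.fixture
def star4() -> nx.Graph:
    """Star with 4 leaves; center node 0."""
    return nx.star_graph(4)


@pytest.fixture
def path3() -> nx.Graph:
    return nx.path_graph(3)


@pytest.fixture
def two_nodes_one_edge() -> nx.Graph:
    G = nx.Graph()
    G.add_edge(0, 1)
    return G


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    return nx.gnp_random_graph(n, p, seed=seed)


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    """G(n, p) conditioned on connectivity (deterministic retry schedule)."""
    for offset in range(1000):
        G = nx.gnp_random_graph(n, p, seed=seed * 1000 + offset)
        if n == 0 or nx.is_connected(G):
            return G
    raise RuntimeError("could not draw a connected graph")


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=7)


@pytest.fixture
def small_config() -> SimulationConfig:
    """Feasible reduced design: still satisfies the hub-wiring minimum."""
    return SimulationConfig(
        n_genes=300, n_samples_per_group=6, n_de_genes=60, n_hubs=2, rng_seed=11
    )
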