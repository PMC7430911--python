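"""Shared fixtures: tiny graphs, a small planted-module dataset."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from funcprop.propagation import PropagationNetwork
from funcprop.synthetic import SyntheticConfig, generate


def weighted_graph(edges) -> nx.Graph:
    """Build an undirected graph from (a, b, w) triples."""
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=float(w))
    return g


def pn_from_graph(g: nx.Graph) -> PropagationNetwork:
    return PropagationNetwork.from_graph(g)


def random_weighted_graph(rng: np.random.Generator, n: int, p: float,
                          w_lo: float = 0.1, w_hi: float = 1.0) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in range(n)})
    for a, b in g.edges:
        g[a][b]["weight"] = float(rng.uniform(w_lo, w_hi))
    return g


@pytest.fixture(scope="session")
def small_dataset():
    """3 planted modules of 10-14 proteins; clear community signal."""
    cfg = SyntheticConfig(n_modules=3, module_size=(10, 14), p_in=0.5,
                          p_out=0.02, funcs_per_module=2,
                          annotation_noise=0.0, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def acceptance_dataset():
    """The planted-recovery study conditions: 10 modules x 20 proteins."""
    cfg = SyntheticConfig(n_modules=10, module_size=(20, 20), p_in=0.3,
                          p_out=0.01, funcs_per_module=3,
                          annotation_noise=0.0, seed=7)
    return generate(cfg)
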