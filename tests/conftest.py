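import itertools

import networkx as nx
import numpy as np
import pytest

from prizenet.prize_network import PCSFInstance


@pytest.fixture
def t1_graph():
    """Three-node worked instance: cheap AB edge, expensive detours via C."""
    g = nx.Graph()
    g.add_edge("A", "B", cost=1.0)
    g.add_edge("A", "C", cost=10.0)
    g.add_edge("B", "C", cost=10.0)
    return g


@pytest.fixture
def t1_instance(t1_graph):
    return PCSFInstance(
        graph=t1_graph, prizes={"A": 5.0, "B": 5.0}, beta=1.0, omega=2.0
    )


def random_instance(rng: np.random.Generator, max_nodes: int = 10) -> PCSFInstance:
    """Small random PCSF instance for oracle-vs-heuristic comparisons."""
    n = int(rng.integers(4, max_nodes + 1))
    g = nx.Graph()
    g.add_nodes_from(f"N{i}" for i in range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.4:
            g.add_edge(f"N{i}", f"N{j}", cost=float(rng.uniform(0.1, 2.0)))
    prizes = {
        f"N{i}": float(rng.exponential(1.5))
        for i in range(n)
        if rng.random() < 0.6
    }
    omega = float(rng.uniform(0.5, 3.0))
    return PCSFInstance(graph=g, prizes=prizes, beta=1.0, omega=omega)


@pytest.fixture
def two_cliques():
    """Two 5-cliques joined by a single bridge edge."""
    g = nx.Graph()
    for base in (0, 5):
        for i, j in itertools.combinations(range(base, base + 5), 2):
            g.add_edge(i, j)
    g.add_edge(0, 5)
    return g
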