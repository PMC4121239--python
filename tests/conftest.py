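from __future__ import annotations

import random

import networkx as nx
import pytest

from noderole import synthetic


@pytest.fixture
def star5() -> nx.Graph:
    """Star with hub 0 and leaves 1-4."""
    return synthetic.star(5)


@pytest.fixture
def triangle() -> nx.Graph:
    return synthetic.complete(3)


@pytest.fixture
def dstar() -> nx.Graph:
    """Canonical 13-node double-star fixture (hubs v1/v13, bridge v7)."""
    return synthetic.double_star()


@pytest.fixture(scope="session")
def karate() -> nx.Graph:
    return synthetic.karate_graph()


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Small seeded G(n, p) used for oracle cross-checks."""
    return nx.gnp_random_graph(n, p, seed=seed)


def random_connected_graphs(count: int, max_n: int = 8, seed: int = 20240) -> list[nx.Graph]:
    """A seeded sample of small connected graphs with 2..max_n nodes."""
    rng = random.Random(seed)
    out = []
    attempts = 0
    while len(out) < count and attempts < count * 50:
        attempts += 1
        n = rng.randint(2, max_n)
        p = rng.uniform(0.25, 0.9)
        g = nx.gnp_random_graph(n, p, seed=rng.randrange(2**31))
        if nx.is_connected(g):
            out.append(g)
    return out
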