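"""Seeded generators for test topologies.

The model families mirror the study conditions the role-identification
method was evaluated under: Erdos-Renyi, Barabasi-Albert and
Watts-Strogatz networks with 200 nodes and mean degree 4, ten random
replicates per family, plus a 13-node double-star fixture whose roles
are known by construction and a handful of named graphs (star, path,
cycle, complete) used as analytic oracles.

All generators are deterministic under a seed; replicate seeds for a
collection are spawned from one base seed via numpy's SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ModelSpec",
    "double_star",
    "er_graph",
    "ba_graph",
    "ws_graph",
    "model_graph",
    "model_collection",
    "spawn_seeds",
    "star",
    "path",
    "cycle",
    "complete",
    "karate_graph",
]

_FAMILIES = ("double_star", "er", "ba", "ws", "star", "path", "cycle", "complete")


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2^31) from one base seed."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def double_star(
    n_left: int = 6, n_right: int = 6, asymmetry_edges: int = 1, seed: int | None = None
) -> nx.Graph:
    """Two hub-and-leaf stars joined through a single shared bridge node.

    The left hub is ``v1`` with ``n_left - 1`` private leaves; the right
    hub is the last node (``v13`` in the canonical 13-node fixture) with
    ``n_right - 1`` leaves; the bridge (``v7`` canonically) is adjacent
    to both hubs and nothing else.  ``asymmetry_edges`` extra leaf-leaf
    edges pair the i-th left leaf with the i-th right leaf: the hubs
    keep equal degree and stay exchangeable under an automorphism (so
    they tie on every whole-graph indicator) while their two-layer ego
    networks differ.  By construction the hubs are the cores and the
    shared neighbor is the bridge.

    ``seed`` is accepted for interface uniformity; the construction is
    deterministic.
    """
    if n_left < 2 or n_right < 2:
        raise ValueError("n_left and n_right must be >= 2")
    if not (0 <= asymmetry_edges <= min(n_left, n_right) - 1):
        raise ValueError("asymmetry_edges must be between 0 and min(n_left, n_right) - 1")
    g = nx.Graph()
    left_hub = "v1"
    left_leaves = [f"v{i}" for i in range(2, n_left + 1)]
    bridge = f"v{n_left + 1}"
    right_leaves = [f"v{n_left + 1 + i}" for i in range(1, n_right)]
    right_hub = f"v{n_left + n_right + 1}"
    for leaf in left_leaves:
        g.add_edge(left_hub, leaf)
    for leaf in right_leaves:
        g.add_edge(right_hub, leaf)
    g.add_edge(left_hub, bridge)
    g.add_edge(bridge, right_hub)
    for i in range(asymmetry_edges):
        g.add_edge(left_leaves[i], right_leaves[i])
    return g


def er_graph(n: int = 200, k: float = 4.0, seed: int | None = None) -> nx.Graph:
    """Erdos-Renyi G(n, p) with p = k/(n-1) targeting mean degree k."""
    if n < 2 or k <= 0:
        raise ValueError("need n >= 2 and k > 0")
    return nx.gnp_random_graph(n, k / (n - 1), seed=seed)


def ba_graph(n: int = 200, m: int = 2, seed: int | None = None) -> nx.Graph:
    """Barabasi-Albert preferential attachment (m edges per new node)."""
    if m < 1 or n <= m:
        raise ValueError("need 1 <= m < n")
    return nx.barabasi_albert_graph(n, m, seed=seed)


def ws_graph(n: int = 200, k: int = 4, p: float = 0.1, seed: int | None = None) -> nx.Graph:
    """Watts-Strogatz ring lattice (even degree k) with rewiring
    probability p (default 0.1)."""
    if k % 2 != 0 or k < 2:
        raise ValueError(f"WS lattice degree must be a positive even integer, got {k}")
    if n <= k:
        raise ValueError("need n > k")
    return nx.watts_strogatz_graph(n, k, p, seed=seed)


@dataclass(frozen=True)
class ModelSpec:
    """Family + parameters + seed; identical spec and seed give an
    identical graph."""

    family: str
    n: int = 200
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")


def model_graph(spec: ModelSpec) -> nx.Graph:
    """Build the graph a ModelSpec describes."""
    fam, n, p, seed = spec.family, spec.n, spec.params, spec.seed
    if fam == "double_star":
        return double_star(
            p.get("n_left", 6), p.get("n_right", 6), p.get("asymmetry_edges", 1), seed
        )
    if fam == "er":
        return er_graph(n, p.get("k", 4.0), seed)
    if fam == "ba":
        return ba_graph(n, p.get("m", 2), seed)
    if fam == "ws":
        return ws_graph(n, p.get("k", 4), p.get("p", 0.1), seed)
    if fam == "star":
        return star(n)
    if fam == "path":
        return path(n)
    if fam == "cycle":
        return cycle(n)
    return complete(n)


def model_collection(
    family: str, n_graphs: int = 10, seed: int = 0, n: int = 200, **params
) -> list[nx.Graph]:
    """A seeded collection of random model networks (the study condition:
    10 replicates per family)."""
    return [
        model_graph(ModelSpec(family=family, n=n, params=params, seed=s))
        for s in spawn_seeds(seed, n_graphs)
    ]


def star(n: int = 5) -> nx.Graph:
    """Star S_n: hub 0 with n-1 leaves."""
    return nx.star_graph(n - 1)


def path(n: int) -> nx.Graph:
    return nx.path_graph(n)


def cycle(n: int) -> nx.Graph:
    return nx.cycle_graph(n)


def complete(n: int) -> nx.Graph:
    return nx.complete_graph(n)


def karate_graph() -> nx.Graph:
    """Zachary's karate club (34 nodes, 78 edges), unweighted."""
    g = nx.karate_club_graph()
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from(g.edges())
    return out
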