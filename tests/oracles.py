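"""Independent brute-force oracles for small graphs.

Every routine here re-derives an indicator from first principles —
exhaustive path enumeration, a dense eigendecomposition, an explicit
matrix inverse, or direct evaluation of Burt's redundancy formulas —
using the graph only as an adjacency container.  They deliberately share
no code path with the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def _adjacency(g) -> dict:
    return {v: set(g.neighbors(v)) for v in g.nodes()}


def _all_paths(adj: dict, src, dst) -> list[list]:
    """All simple paths from src to dst by DFS."""
    out: list[list] = []
    stack = [(src, [src])]
    while stack:
        node, path = stack.pop()
        if node == dst:
            out.append(path)
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))
    return out


def brute_betweenness(g) -> dict:
    """Absolute betweenness by enumerating every simple path of every pair
    and keeping the shortest ones."""
    adj = _adjacency(g)
    nodes = list(g.nodes())
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_paths(adj, s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        for p in shortest:
            for v in p[1:-1]:
                score[v] += 1.0 / len(shortest)
    return score


def brute_ego_betweenness(g) -> dict:
    """Betweenness of the ego inside its one-layer ego network, via the
    same path enumeration."""
    out = {}
    for v in g.nodes():
        members = {v, *g.neighbors(v)}
        sub = g.subgraph(members)
        out[v] = brute_betweenness(sub)[v]
    return out


def eigh_eigenvector(g, nodelist=None) -> dict:
    """Principal adjacency eigenvector via dense symmetric
    eigendecomposition, max-normalized."""
    import networkx as nx

    nodes = nodelist or list(g.nodes())
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    if not a.any():
        return {v: 0.0 for v in nodes}
    _, vecs = np.linalg.eigh(a)
    x = np.abs(vecs[:, -1])
    x = x / x.max()
    return dict(zip(nodes, x))


def inverse_information_centrality(g, regularization: str = "identity") -> dict:
    """Information centrality from the explicit dense inverse of
    B = D - A + J, per connected component."""
    import networkx as nx

    out = {}
    for comp in nx.connected_components(g):
        nodes = list(comp)
        n = len(nodes)
        if n == 1:
            out[nodes[0]] = 0.0
            continue
        a = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes, weight=None)
        j = np.eye(n) if regularization == "identity" else np.ones((n, n))
        c = np.linalg.inv(np.diag(a.sum(axis=1)) - a + j)
        t = np.trace(c)
        r = c.sum(axis=1)[0]
        for i, v in enumerate(nodes):
            out[v] = 1.0 / (c[i, i] + (t - 2.0 * r) / n)
    return out


def burt_measures(g) -> dict:
    """Burt's effective size, efficiency, constraint and hierarchy from
    direct evaluation of the defining sums with proportional tie
    strengths p_ij = a_ij / k_i and m_jq = a_jq / max_q' a_jq'.

    Returns node -> (effective_size, efficiency, constraint, hierarchy).
    """
    adj = _adjacency(g)
    out = {}
    for v in g.nodes():
        neigh = sorted(adj[v], key=str)
        k = len(neigh)
        if k == 0:
            out[v] = (0.0, 0.0, 0.0, 0.0)
            continue
        p = {q: 1.0 / k for q in neigh}
        # effective size: sum_j (1 - sum_q p_vq * m_jq), q over shared contacts
        es = 0.0
        for j in neigh:
            redundancy = 0.0
            if adj[j]:
                m_max = 1.0  # unweighted: max_q' a_jq' = 1 whenever j has a tie
                for q in neigh:
                    if q != j and q in adj[j]:
                        redundancy += p[q] * (1.0 / m_max)
            es += 1.0 - redundancy
        # constraint: sum_j (p_vj + sum_q p_vq p_qj)^2
        terms = {}
        for j in neigh:
            indirect = 0.0
            for q in neigh:
                if q != j and j in adj[q]:
                    terms_q = len(adj[q])
                    indirect += p[q] * (1.0 / terms_q)
            terms[j] = (p[j] + indirect) ** 2
        c = sum(terms.values())
        # hierarchy: Coleman-Theil concentration of constraint terms
        if k <= 1 or c <= 0:
            h = 0.0
        else:
            mean = c / k
            h = sum(
                (t / mean) * np.log(t / mean) for t in terms.values() if t > 0
            ) / (k * np.log(k))
        out[v] = (es, es / k, c, float(h))
    return out


def pagerank_star(n_leaves: int, damping: float = 0.85) -> tuple[float, float]:
    """Closed-form PageRank of a star: solve the two-state fixed point
    (hub score h, leaf score l) by hand.

    h = (1-d)/N + d * n_leaves * l ;  l = (1-d)/N + d * h / n_leaves.
    """
    n = n_leaves + 1
    a = np.array([[1.0, -damping * n_leaves], [-damping / n_leaves, 1.0]])
    b = np.array([(1 - damping) / n, (1 - damping) / n])
    h, leaf = np.linalg.solve(a, b)
    return float(h), float(leaf)
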