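"""PageRank and HITS reference scorers, and rank-agreement measures.

These are the standard comparison baselines for importance rankings.
On an undirected graph each edge acts as two directed arcs for
PageRank; HITS hub and authority scores coincide and equal eigenvector
centrality (reported max-normalized for comparability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
from scipy import stats

__all__ = ["BaselineScores", "pagerank", "hits", "rank_agreement"]


@dataclass(frozen=True)
class BaselineScores:
    """Node -> score mapping with method tag and solver metadata."""

    scores: dict[Hashable, float]
    method: str
    meta: dict = field(default_factory=dict)

    def __getitem__(self, node: Hashable) -> float:
        return self.scores[node]


def pagerank(g: nx.Graph, damping: float = 0.85, tol: float = 1e-10) -> BaselineScores:
    """PageRank with uniform teleportation; scores sum to 1.

    Dangling (isolated) nodes distribute their mass uniformly.  Raises
    on non-convergence.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot rank an empty graph")
    try:
        pr = nx.pagerank(g, alpha=damping, tol=tol, max_iter=1000)
    except nx.PowerIterationFailedConvergence as exc:
        raise ArithmeticError(f"PageRank failed to converge: {exc}") from exc
    return BaselineScores(scores=pr, method="pagerank", meta={"damping": damping, "tol": tol})


def hits(g: nx.Graph, tol: float = 1e-10) -> tuple[BaselineScores, BaselineScores]:
    """HITS (hub, authority) scores, max-normalized.

    On an undirected graph the hub and authority fixed points coincide
    with the principal adjacency eigenvector; it is obtained here by a
    dense symmetric eigendecomposition (exact up to machine precision,
    so ``tol`` is recorded as metadata only).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot rank an empty graph")
    nodes = list(g.nodes())
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    if not a.any():
        scores = {v: 0.0 for v in nodes}
    else:
        _, vecs = np.linalg.eigh(a)
        x = np.abs(vecs[:, -1])
        x /= x.max()
        scores = dict(zip(nodes, map(float, x)))
    meta = {"tol": tol, "solver": "dense eigendecomposition"}
    return (
        BaselineScores(scores=dict(scores), method="hits_hub", meta=meta),
        BaselineScores(scores=dict(scores), method="hits_authority", meta=meta),
    )


def _top_k(scores: Mapping[Hashable, float], k: int) -> set:
    """Top-k labels by score; tie groups truncated deterministically by
    label order."""
    ordered = sorted(scores, key=lambda v: (-scores[v], str(v)))
    return set(ordered[:k])


def rank_agreement(
    a: Mapping[Hashable, float], b: Mapping[Hashable, float], top_k: int
) -> tuple[float, float]:
    """(Spearman correlation, top-k overlap fraction) of two score vectors
    over the same node set."""
    if set(a) != set(b):
        raise ValueError("score vectors cover different node sets")
    if not (1 <= top_k <= len(a)):
        raise ValueError(f"top_k must be in [1, {len(a)}], got {top_k}")
    nodes = list(a)
    rho = stats.spearmanr([a[v] for v in nodes], [b[v] for v in nodes]).statistic
    overlap = len(_top_k(a, top_k) & _top_k(b, top_k)) / top_k
    return float(rho), overlap
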