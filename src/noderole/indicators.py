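"""Node-level topology indicators.

Thirteen indicators over a closed vocabulary: ten classical measures
(degree, closeness, betweenness, eigenvector, information centrality,
clustering, and Burt's four structural-hole measures) plus three
ego-network variants (ego-betweenness, ego-eigenvector,
ego-information).  Ego variants need only a node's local neighborhood:
ego-betweenness and ego-information are computed inside the one-layer
ego network, ego-eigenvector inside the two-layer ego network.

Conventions for degenerate nodes: clustering is 0 for degree < 2;
structural-hole measures are all 0 for isolated nodes; betweenness,
closeness and information centrality are computed within connected
components, and pairs in different components contribute nothing.
"""

from __future__ import annotations

import logging
import warnings
from typing import Hashable

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

from .graph import ego_network

logger = logging.getLogger(__name__)

#: Closed indicator vocabulary (column order of :func:`indicator_table`).
VOCABULARY = (
    "degree",
    "closeness",
    "betweenness",
    "ego_betweenness",
    "eigenvector",
    "ego_eigenvector",
    "information",
    "ego_information",
    "clustering",
    "effective_size",
    "efficiency",
    "constraint",
    "hierarchy",
)

__all__ = [
    "VOCABULARY",
    "degree",
    "clustering",
    "betweenness",
    "ego_betweenness",
    "closeness",
    "eigenvector",
    "information_centrality",
    "structural_holes",
    "indicator_table",
]


def degree(g: nx.Graph, relative: bool = False) -> dict[Hashable, float]:
    """Raw degree k_i, or relative degree k_i/(N-1)."""
    n = g.number_of_nodes()
    if relative:
        denom = n - 1
        return {v: (k / denom if denom > 0 else 0.0) for v, k in g.degree()}
    return {v: float(k) for v, k in g.degree()}


def clustering(g: nx.Graph) -> dict[Hashable, float]:
    """Local clustering coefficient: edge density among a node's neighbors
    (0 for degree < 2)."""
    return {v: float(c) for v, c in nx.clustering(g).items()}


def betweenness(g: nx.Graph) -> dict[Hashable, float]:
    """Absolute (unnormalized) shortest-path betweenness.

    Each unordered pair (i, j), i != v != j, in the same component
    contributes g_ij(v)/g_ij, the fraction of shortest i-j paths passing
    through v.
    """
    return nx.betweenness_centrality(g, normalized=False)


def ego_betweenness(g: nx.Graph) -> dict[Hashable, float]:
    """Betweenness of each node computed inside its one-layer ego network."""
    out = {}
    for v in g.nodes():
        eg = ego_network(g, v, layers=1)
        out[v] = nx.betweenness_centrality(eg, normalized=False)[v]
    return out


def closeness(g: nx.Graph) -> dict[Hashable, float]:
    """Relative closeness (n_c - 1) / sum of distances within the node's
    component; 0 for isolated nodes."""
    return nx.closeness_centrality(g, wf_improved=False)


def _principal_eigenvector(a: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Principal eigenvector of a non-negative symmetric matrix by power
    iteration, normalized to max component 1.

    Iterates on A + I (same eigenvectors, and primitive on connected
    graphs, so bipartite +/-lambda pairs cannot stall convergence).
    Deterministic uniform start; convergence when successive
    max-normalized iterates differ by < ``tol`` in max-norm.  An all-zero
    matrix (edgeless graph) yields the zero vector with a warning.  On a
    disconnected graph the start vector breaks ties between components of
    equal spectral radius (mass settles on components attaining the
    overall radius).
    """
    n = a.shape[0]
    x = np.ones(n)
    if not a.any():
        warnings.warn("edgeless graph: eigenvector centrality is identically zero")
        return np.zeros(n)
    for _ in range(max_iter):
        y = a @ x + x
        m = y.max()
        if m <= 0:
            warnings.warn("eigenvector iteration collapsed; returning zeros")
            return np.zeros(n)
        y /= m
        if np.abs(y - x).max() < tol:
            return y
        x = y
    logger.warning("power iteration hit the %d-iteration cap", max_iter)
    return x


def eigenvector(g: nx.Graph, ego: bool = False) -> dict[Hashable, float]:
    """Eigenvector centrality: a node's component of the adjacency matrix's
    principal eigenvector, max-normalized.

    With ``ego=True`` each node's value comes from the principal
    eigenvector of its own two-layer ego network (max-normalized within
    that subgraph), so the measure needs only local topology.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("eigenvector centrality of an empty graph is undefined")
    if not ego:
        nodes = list(g.nodes())
        x = _principal_eigenvector(nx.to_numpy_array(g, nodelist=nodes))
        return dict(zip(nodes, x))
    out = {}
    for v in g.nodes():
        eg = ego_network(g, v, layers=2)
        nodes = list(eg.nodes())
        x = _principal_eigenvector(nx.to_numpy_array(eg, nodelist=nodes))
        out[v] = x[nodes.index(v)]
    return out


def _information_component(a: np.ndarray, regularization: str) -> np.ndarray:
    """Stephenson-Zelen information centrality for one connected component.

    B = D - A + J with J the all-ones matrix ("ones", the classical form)
    or the identity ("identity").  With C = B^-1, T = trace(C) and R the
    (constant) row sum of C, node v scores 1 / (C_vv + (T - 2R)/n).
    """
    n = a.shape[0]
    d = np.diag(a.sum(axis=1))
    if regularization == "ones":
        b = d - a + np.ones((n, n))
    elif regularization == "identity":
        b = d - a + np.eye(n)
    else:
        raise ValueError(f"regularization must be 'identity' or 'ones', got {regularization!r}")
    try:
        c = scipy.linalg.solve(b, np.eye(n), assume_a="pos")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - cannot occur when connected
        raise ArithmeticError(f"information matrix is singular: {exc}") from exc
    t = np.trace(c)
    r = c[0].sum()
    return 1.0 / (np.diag(c) + (t - 2.0 * r) / n)


def information_centrality(
    g: nx.Graph, ego: bool = False, regularization: str = "identity"
) -> dict[Hashable, float]:
    """Information centrality, computed per connected component.

    The information matrix is B = D - A + J on the component, with J the
    identity by default (``regularization="identity"``); the classical
    Stephenson-Zelen all-ones J is available as ``regularization="ones"``.
    Both choices give B constant row sums, so the "any row sum" term R is
    well defined.  Isolated nodes score 0.  With ``ego=True`` each node's
    value is computed inside its one-layer ego network.
    """
    if ego:
        out = {}
        for v in g.nodes():
            eg = ego_network(g, v, layers=1)
            nodes = list(eg.nodes())
            vals = _information_component(nx.to_numpy_array(eg, nodelist=nodes), regularization)
            out[v] = float(vals[nodes.index(v)])
        return out
    out = {}
    for comp in nx.connected_components(g):
        nodes = list(comp)
        if len(nodes) == 1:
            out[nodes[0]] = 0.0
            continue
        a = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes)
        vals = _information_component(a, regularization)
        out.update(zip(nodes, map(float, vals)))
    return out


def _hierarchy_one(g: nx.Graph, v: Hashable, constraint_v: float) -> float:
    """Burt's hierarchy: Coleman-Theil concentration of the per-neighbor
    constraint terms c_vj around their mean C_v/k."""
    neigh = list(g.neighbors(v))
    k = len(neigh)
    if k <= 1 or constraint_v <= 0:
        return 0.0
    mean = constraint_v / k
    total = 0.0
    for j in neigh:
        ratio = nx.local_constraint(g, v, j) / mean
        if ratio > 0:
            total += ratio * np.log(ratio)
    return float(total / (k * np.log(k)))


def structural_holes(g: nx.Graph) -> pd.DataFrame:
    """Burt's structural-hole measures with proportional tie strengths
    p_ij = a_ij / k_i.

    Columns: ``effective_size`` (non-redundant portion of the ego's
    contacts), ``efficiency`` (effective size / degree), ``constraint``
    (how concentrated the ego's ties are in a closed neighborhood) and
    ``hierarchy`` (Coleman-Theil concentration of constraint across
    contacts).  Isolated nodes get 0 for all four, with a warning.
    """
    nodes = list(g.nodes())
    es = nx.effective_size(g)
    con = nx.constraint(g)
    rows = {}
    isolates = 0
    for v in nodes:
        k = g.degree(v)
        if k == 0:
            isolates += 1
            rows[v] = (0.0, 0.0, 0.0, 0.0)
            continue
        e = float(es[v])
        c = float(con[v])
        rows[v] = (e, e / k, c, _hierarchy_one(g, v, c))
    if isolates:
        warnings.warn(f"{isolates} isolated node(s): structural-hole measures set to 0")
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["effective_size", "efficiency", "constraint", "hierarchy"],
    ).loc[nodes]


def indicator_table(
    g: nx.Graph,
    which: tuple[str, ...] | list[str] | None = None,
    regularization: str = "identity",
) -> pd.DataFrame:
    """Node x indicator table over (a subset of) the 13-indicator vocabulary.

    Rows are node labels in graph order; columns follow ``VOCABULARY``
    order.  Unknown indicator names raise ``KeyError``.
    """
    if which is None:
        which = VOCABULARY
    unknown = [w for w in which if w not in VOCABULARY]
    if unknown:
        raise KeyError(f"unknown indicator(s) {unknown}; vocabulary: {list(VOCABULARY)}")
    nodes = list(g.nodes())
    cols: dict[str, dict] = {}
    wanted = set(which)
    if "degree" in wanted:
        cols["degree"] = degree(g)
    if "closeness" in wanted:
        cols["closeness"] = closeness(g)
    if "betweenness" in wanted:
        cols["betweenness"] = betweenness(g)
    if "ego_betweenness" in wanted:
        cols["ego_betweenness"] = ego_betweenness(g)
    if "eigenvector" in wanted:
        cols["eigenvector"] = eigenvector(g)
    if "ego_eigenvector" in wanted:
        cols["ego_eigenvector"] = eigenvector(g, ego=True)
    if "information" in wanted:
        cols["information"] = information_centrality(g, regularization=regularization)
    if "ego_information" in wanted:
        cols["ego_information"] = information_centrality(g, ego=True, regularization=regularization)
    if "clustering" in wanted:
        cols["clustering"] = clustering(g)
    if wanted & {"effective_size", "efficiency", "constraint", "hierarchy"}:
        sh = structural_holes(g)
        for name in ("effective_size", "efficiency", "constraint", "hierarchy"):
            if name in wanted:
                cols[name] = sh[name].to_dict()
    frame = pd.DataFrame(index=pd.Index(nodes, name="node"))
    for name in VOCABULARY:
        if name in wanted:
            frame[name] = pd.Series(cols[name])
    return frame
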