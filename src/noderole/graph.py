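"""Graph loading, coercion and ego-network extraction.

All analyses in this package operate on simple undirected unweighted
graphs.  Input files in any supported format (edge list, GML, GraphML)
are coerced on load: directed edges are symmetrized, edge weights and
other attributes are dropped, self-loops and duplicate edges removed.
Node labels are opaque and preserved in first-seen order; results are
always reported against labels, never internal indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "GraphFormatError",
    "EmptyGraphError",
    "CoercionReport",
    "coerce",
    "load_graph",
    "save_graph",
    "drop_isolates",
    "ego_network",
]

_FORMATS = ("edgelist", "gml", "graphml")
_SUFFIX_FORMAT = {
    ".gml": "gml",
    ".graphml": "graphml",
    ".xml": "graphml",
    ".edgelist": "edgelist",
    ".edges": "edgelist",
    ".txt": "edgelist",
    ".csv": "edgelist",
    ".tsv": "edgelist",
}


class GraphFormatError(ValueError):
    """A graph file could not be parsed under the named format."""


class EmptyGraphError(ValueError):
    """The loaded graph contains no nodes."""


@dataclass(frozen=True)
class CoercionReport:
    """Counts of records dropped while coercing to simple undirected form."""

    self_loops: int = 0
    duplicate_edges: int = 0
    weights_dropped: int = 0

    @property
    def total_dropped(self) -> int:
        return self.self_loops + self.duplicate_edges


def coerce(graph: nx.Graph) -> tuple[nx.Graph, CoercionReport]:
    """Coerce any networkx graph to a simple undirected unweighted graph.

    Directed edges are symmetrized (u->v and v->u collapse onto one
    undirected edge), self-loops are removed, multi-edges and reciprocal
    duplicates are merged, and all node/edge attributes are discarded.
    """
    weights = sum(1 for *_e, d in graph.edges(data=True) if d)
    loops = 0
    dup = 0
    out = nx.Graph()
    out.add_nodes_from(graph.nodes())
    for u, v in graph.edges():
        if u == v:
            loops += 1
        elif out.has_edge(u, v):
            dup += 1
        else:
            out.add_edge(u, v)
    report = CoercionReport(self_loops=loops, duplicate_edges=dup, weights_dropped=weights)
    if report.total_dropped or report.weights_dropped:
        logger.info(
            "coerced graph: dropped %d self-loop(s), %d duplicate edge(s), %d weight(s)",
            report.self_loops, report.duplicate_edges, report.weights_dropped,
        )
    return out, report


def _parse_edgelist(path: Path) -> nx.Graph:
    """Edge-list dialect: whitespace- or comma-separated, first two tokens
    are endpoints, extra tokens ignored, '#' lines skipped."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected at least two tokens, got {line!r}"
                )
            u, v = tokens[0], tokens[1]
            g.add_node(u)
            g.add_node(v)
            g.add_edge(u, v)
    return g


def load_graph(path: str | Path, format: str | None = None) -> nx.Graph:
    """Load a graph file and coerce it to simple undirected unweighted form.

    Parameters
    ----------
    path : file path.
    format : one of ``edgelist``, ``gml``, ``graphml``; inferred from the
        file suffix when omitted (unknown suffixes fall back to edgelist).

    Raises
    ------
    FileNotFoundError, GraphFormatError, EmptyGraphError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = _SUFFIX_FORMAT.get(path.suffix.lower(), "edgelist")
    if format not in _FORMATS:
        raise ValueError(f"unknown graph format {format!r}; expected one of {_FORMATS}")
    try:
        if format == "edgelist":
            raw = _parse_edgelist(path)
        elif format == "gml":
            raw = nx.read_gml(path)
        else:
            raw = nx.read_graphml(path)
    except GraphFormatError:
        raise
    except Exception as exc:  # malformed GML/GraphML
        raise GraphFormatError(f"could not parse {path} as {format}: {exc}") from exc
    g, _ = coerce(raw)
    if g.number_of_nodes() == 0:
        raise EmptyGraphError(f"{path} contains no nodes")
    return g


def save_graph(g: nx.Graph, path: str | Path, format: str | None = None) -> None:
    """Write a graph in edge-list, GML or GraphML form."""
    path = Path(path)
    if format is None:
        format = _SUFFIX_FORMAT.get(path.suffix.lower(), "edgelist")
    if format == "edgelist":
        with open(path, "w") as fh:
            for u, v in g.edges():
                fh.write(f"{u}\t{v}\n")
    elif format == "gml":
        nx.write_gml(g, path, stringizer=str)
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {format!r}; expected one of {_FORMATS}")


def drop_isolates(g: nx.Graph) -> nx.Graph:
    """Return the subgraph on nodes with degree >= 1 (edges unchanged)."""
    keep = [v for v, k in g.degree() if k >= 1]
    return g.subgraph(keep).copy()


def ego_network(g: nx.Graph, ego: Hashable, layers: int = 1) -> nx.Graph:
    """Extract the one- or two-layer ego network of a node.

    The one-layer ego network of v is the induced subgraph on v and its
    neighbors.  The two-layer ego network is the union of the one-layer
    ego networks of v and its neighbors: it spans the radius-2 ball
    around v, but an edge between two distance-2 nodes is kept only when
    both endpoints lie in a common neighbor's ego network.  The ego is
    always present.
    """
    if ego not in g:
        raise KeyError(f"node {ego!r} not in graph")
    if layers == 1:
        return g.subgraph([ego, *g.neighbors(ego)]).copy()
    if layers == 2:
        out = nx.Graph()
        out.add_node(ego)
        for u in (ego, *g.neighbors(ego)):
            one = g.subgraph([u, *g.neighbors(u)])
            out.add_nodes_from(one.nodes())
            out.add_edges_from(one.edges())
        return out
    raise ValueError(f"layers must be 1 or 2, got {layers}")


def mean_degree(g: nx.Graph) -> float:
    """Mean degree 2M/N."""
    n = g.number_of_nodes()
    if n == 0:
        raise EmptyGraphError("mean degree of an empty graph is undefined")
    return 2.0 * g.number_of_edges() / n
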