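"""EIMI: Evaluation of Importance based on Multi-Indicator.

A node's importance is the weighted sum of three max-normalized
indicators chosen for their strong mutual correlation and complementary
sociological readings:

    I_i = alpha * I_D(i) + beta * I_EB(i) + gamma * I_E(i)

where I_D is normalized degree (how many ties the node has), I_EB is
normalized ego-betweenness (its control over exchanges between its
contacts) and I_E is normalized eigenvector centrality (how well it is
connected to other important nodes).  The ``global`` variant takes the
eigenvector component from the whole graph; the ``ego`` variant takes
it from each node's two-layer ego network, so that every component can
be computed from local topology alone.  Weights default to equal
(alpha = beta = gamma = 1), making totals live in [0, 3]; rankings are
invariant to the common scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import pandas as pd

from . import indicators

__all__ = ["EimiWeights", "ImportanceScore", "normalize", "eimi"]

_VARIANTS = ("global", "ego")


@dataclass(frozen=True)
class EimiWeights:
    """Non-negative indicator weights (alpha: degree, beta: ego-betweenness,
    gamma: eigenvector); not all zero."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            w = getattr(self, name)
            if not (w >= 0.0 and w < float("inf")):
                raise ValueError(f"weight {name} must be finite and >= 0, got {w}")
        if self.alpha == self.beta == self.gamma == 0.0:
            raise ValueError("at least one weight must be positive")


def normalize(values: Mapping[Hashable, float], scheme: str = "max") -> dict[Hashable, float]:
    """Normalize non-negative indicator values to [0, 1].

    ``max`` (default) divides by the maximum, keeping zeros at zero and
    putting the top node at 1; ``minmax`` maps the minimum to 0 as well.
    All-equal input maps to all zeros under minmax and to all ones under
    max (all zeros if the common value is 0).
    """
    vals = dict(values)
    if any(v < 0 for v in vals.values()):
        raise ValueError("indicator values must be non-negative")
    if not vals:
        return {}
    hi = max(vals.values())
    if scheme == "max":
        if hi == 0:
            return {k: 0.0 for k in vals}
        return {k: v / hi for k, v in vals.items()}
    if scheme == "minmax":
        lo = min(vals.values())
        span = hi - lo
        if span == 0:
            return {k: 0.0 for k in vals}
        return {k: (v - lo) / span for k, v in vals.items()}
    raise ValueError(f"scheme must be 'max' or 'minmax', got {scheme!r}")


@dataclass(frozen=True)
class ImportanceScore:
    """Per-node EIMI result: the three normalized components and the total.

    ``frame`` columns: I_D, I_EB, I_E, total, rank (dense, 1 = most
    important).  The total is recomputable as
    alpha*I_D + beta*I_EB + gamma*I_E.
    """

    frame: pd.DataFrame
    weights: EimiWeights
    variant: str

    @property
    def totals(self) -> dict[Hashable, float]:
        return self.frame["total"].to_dict()

    def top(self, k: int) -> list[Hashable]:
        """The k most important node labels (ties broken by label order)."""
        f = self.frame.copy()
        f["_label"] = f.index.astype(str)
        return list(f.sort_values(["total", "_label"], ascending=[False, True]).index[:k])


def eimi(
    g: nx.Graph,
    weights: EimiWeights | None = None,
    variant: str = "global",
    scheme: str = "max",
) -> ImportanceScore:
    """Score every node's importance from degree, ego-betweenness and
    (ego-)eigenvector centrality.

    Only the eigenvector component switches between variants;
    ego-betweenness is local by construction and is used by both.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
    if g.number_of_nodes() == 0:
        raise ValueError("cannot score an empty graph")
    w = weights or EimiWeights()
    nodes = list(g.nodes())
    i_d = normalize(indicators.degree(g), scheme)
    i_eb = normalize(indicators.ego_betweenness(g), scheme)
    i_e = normalize(indicators.eigenvector(g, ego=(variant == "ego")), scheme)
    frame = pd.DataFrame(
        {
            "I_D": [i_d[v] for v in nodes],
            "I_EB": [i_eb[v] for v in nodes],
            "I_E": [i_e[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    frame["total"] = w.alpha * frame["I_D"] + w.beta * frame["I_EB"] + w.gamma * frame["I_E"]
    frame["rank"] = frame["total"].rank(method="dense", ascending=False).astype(int)
    return ImportanceScore(frame=frame, weights=w, variant=variant)
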