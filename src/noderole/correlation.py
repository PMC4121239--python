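"""Indicator-correlation study.

Pearson and Spearman correlation matrices between indicator columns
within one network, and mean +/- SD aggregation of those matrices over a
collection of networks.  Strong, stable cross-network correlations are
what justifies scoring node importance with a small set of mutually
correlated indicators: an individual node whose indicator relationship
departs from the network-wide statistical pattern is thereby outlined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["correlation_matrix", "CorrelationSummary", "aggregate"]

_METHODS = ("pearson", "spearman")


def correlation_matrix(table: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Correlation matrix between the indicator columns of one network.

    Spearman uses mid-ranks for ties.  Constant columns have no defined
    correlation: their off-diagonal entries are NaN (reported with a
    warning, never silently 0); the diagonal is 1 by convention.

    Raises ``ValueError`` for fewer than 3 nodes.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if len(table) < 3:
        raise ValueError(f"need at least 3 nodes to correlate, got {len(table)}")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant column(s) {constant}: correlations undefined (NaN)")
    mat = table.corr(method=method)
    np.fill_diagonal(mat.values, 1.0)
    return mat


@dataclass
class CorrelationSummary:
    """Mean and SD of per-network correlation matrices over a collection.

    ``mean``/``sd`` map method name -> DataFrame.  SDs use the population
    (divide-by-n) form.  Missing cells (constant columns in any network)
    propagate as NaN.  The per-network matrices are retained.
    """

    matrices: dict[str, list[pd.DataFrame]]
    mean: dict[str, pd.DataFrame] = field(init=False)
    sd: dict[str, pd.DataFrame] = field(init=False)

    def __post_init__(self) -> None:
        self.mean, self.sd = {}, {}
        for method, mats in self.matrices.items():
            if not mats:
                raise ValueError("need at least one network")
            cols = list(mats[0].columns)
            for m in mats[1:]:
                if list(m.columns) != cols:
                    raise ValueError("indicator sets differ across networks")
            stack = np.stack([m.values for m in mats])
            self.mean[method] = pd.DataFrame(stack.mean(axis=0), index=cols, columns=cols)
            self.sd[method] = pd.DataFrame(stack.std(axis=0, ddof=0), index=cols, columns=cols)

    @property
    def n_networks(self) -> int:
        return len(next(iter(self.matrices.values())))

    def pair(self, a: str, b: str, method: str = "pearson") -> tuple[float, float]:
        """(mean, sd) of the correlation between indicators ``a`` and ``b``."""
        return float(self.mean[method].loc[a, b]), float(self.sd[method].loc[a, b])

    def combined_table(self, method: str = "pearson") -> pd.DataFrame:
        """Square table with means in the lower triangle and SDs in the
        upper triangle (the conventional compact display)."""
        mean, sd = self.mean[method], self.sd[method]
        out = mean.copy()
        cols = list(out.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                out.iloc[i, j] = sd.iloc[i, j]
        np.fill_diagonal(out.values, np.nan)
        return out

    def to_long(self) -> pd.DataFrame:
        """Tidy long format: one row per indicator pair with mean and SD
        per method."""
        cols = list(next(iter(self.mean.values())).columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                row: dict = {"indicator_a": a, "indicator_b": b}
                for method in self.mean:
                    m, s = self.pair(a, b, method)
                    row[f"{method}_mean"] = m
                    row[f"{method}_sd"] = s
                rows.append(row)
        return pd.DataFrame(rows)


def aggregate(
    tables: list[pd.DataFrame], methods: tuple[str, ...] = _METHODS
) -> CorrelationSummary:
    """Correlate each network's indicator table and aggregate over the
    collection (element-wise mean and population SD per indicator pair)."""
    if not tables:
        raise ValueError("need at least one network")
    matrices = {m: [correlation_matrix(t, m) for t in tables] for m in methods}
    return CorrelationSummary(matrices)
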