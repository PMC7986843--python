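"""Correlation matrices and their conversion to binary graphs.

A correlation network is built in two steps: estimate the p x p matrix of
pairwise Pearson correlations from an N x p data matrix, then place an edge
between variables i and j whenever ``|C(i, j)| > t`` for a hard threshold
``t``.  A classical alternative, used here as a baseline, places edges where
the Bonferroni-adjusted p-value of the correlation test falls below a
significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinaryGraph",
    "read_data",
    "validate_data",
    "pearson_correlation",
    "validate_correlation",
    "threshold_graph",
    "pvalue_graph",
    "read_edgelist",
]


def read_data(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited text file of observations (rows) by variables (columns).

    The first row must hold the variable names.  Returns a validated
    DataFrame; see :func:`validate_data` for the requirements.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    validate_data(df)
    return df


def validate_data(data: pd.DataFrame) -> None:
    """Check that a data matrix is usable for correlation estimation.

    Requires at least 3 observations and 2 variables, unique variable names,
    numeric values and no missing entries.
    """
    if data.shape[0] < 3:
        raise ValueError(
            f"need at least 3 observations to estimate correlations, got {data.shape[0]}"
        )
    if data.shape[1] < 2:
        raise ValueError(f"need at least 2 variables, got {data.shape[1]}")
    if data.columns.duplicated().any():
        dupes = data.columns[data.columns.duplicated()].tolist()
        raise ValueError(f"duplicate variable names: {dupes}")
    values = data.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = data.columns[np.isnan(values).any(axis=0)].tolist()
        raise ValueError(
            f"missing values in variables {bad}; impute or drop them first"
        )


def _constant_columns(values: np.ndarray, names: Sequence[str]) -> list[str]:
    sd = values.std(axis=0)
    return [str(n) for n, s in zip(names, sd) if s == 0.0]


def pearson_correlation(data: pd.DataFrame) -> pd.DataFrame:
    """Pearson product-moment correlation matrix of the columns of ``data``.

    Returns a symmetric p x p DataFrame with unit diagonal, indexed by the
    variable names in their original column order.

    Raises
    ------
    ValueError
        If any column is constant (its correlation is undefined).
    """
    validate_data(data)
    values = data.to_numpy(dtype=float)
    constant = _constant_columns(values, data.columns)
    if constant:
        raise ValueError(
            f"constant column(s) {constant}: correlation undefined"
        )
    corr = np.corrcoef(values, rowvar=False)
    # guard against floating overshoot of |r| = 1
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return pd.DataFrame(corr, index=data.columns, columns=data.columns)


def validate_correlation(corr: pd.DataFrame) -> None:
    """Check symmetry, unit diagonal and the [-1, 1] range."""
    values = corr.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {values.shape}")
    if not (corr.index == corr.columns).all():
        raise ValueError("correlation matrix row and column labels must match")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=1e-10):
        raise ValueError("correlation matrix diagonal must be 1")
    if np.abs(values).max() > 1.0 + 1e-10:
        raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected simple graph on a fixed, ordered set of labeled nodes.

    The node order is canonical: every downstream partition, stability map
    and serialization refers to nodes by these labels in this order.
    Isolated nodes are legal and retained.
    """

    nodes: tuple
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=bool)
        p = len(self.nodes)
        if adj.shape != (p, p):
            raise ValueError(f"adjacency shape {adj.shape} does not match {p} nodes")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "nodes", tuple(str(n) for n in self.nodes))

    @classmethod
    def from_edges(cls, nodes: Sequence[str], edges: Iterable[tuple]) -> "BinaryGraph":
        nodes = tuple(str(n) for n in nodes)
        index = {n: i for i, n in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for a, b in edges:
            i, j = index[str(a)], index[str(b)]
            if i == j:
                raise ValueError(f"self-loop on node {a!r}")
            adj[i, j] = adj[j, i] = True
        return cls(nodes, adj)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_array(self) -> np.ndarray:
        """Edges as an (m, 2) array of node indices with i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([i, j])

    def edges(self) -> list[tuple]:
        """Edges as unordered label pairs (in canonical index order)."""
        return [(self.nodes[i], self.nodes[j]) for i, j in self.edge_array()]

    def has_edge(self, a: str, b: str) -> bool:
        index = {n: i for i, n in enumerate(self.nodes)}
        return bool(self.adjacency[index[str(a)], index[str(b)]])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    def to_igraph(self):
        import igraph as ig

        return ig.Graph(
            n=self.n_nodes,
            edges=[(int(i), int(j)) for i, j in self.edge_array()],
            vertex_attrs={"name": list(self.nodes)},
        )

    def write_edgelist(self, path, delimiter: str = "\t") -> None:
        """Write edges as two label columns, one edge per line."""
        with open(path, "w") as fh:
            for a, b in self.edges():
                fh.write(f"{a}{delimiter}{b}\n")

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def __eq__(self, other):
        if not isinstance(other, BinaryGraph):
            return NotImplemented
        return self.nodes == other.nodes and np.array_equal(
            self.adjacency, other.adjacency
        )


def read_edgelist(path, nodes: Sequence[str], delimiter: str = "\t") -> BinaryGraph:
    """Read an edge-list text file back into a graph on the given node set."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b = line.split(delimiter)
            edges.append((a, b))
    return BinaryGraph.from_edges(nodes, edges)


def threshold_graph(corr: pd.DataFrame, t: float) -> BinaryGraph:
    """Hard-threshold a correlation matrix into a binary graph.

    An edge joins variables i and j iff ``|C(i, j)| > t`` (strictly).  Any
    ``t >= 1`` therefore yields an edgeless graph on the same nodes; ``t = 0``
    yields the complete graph when no correlation is exactly zero.
    """
    validate_correlation(corr)
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    values = corr.to_numpy(dtype=float)
    adj = np.abs(values) > t
    np.fill_diagonal(adj, False)
    return BinaryGraph(tuple(corr.columns), adj)


def pvalue_graph(data: pd.DataFrame, level: float = 0.05) -> BinaryGraph:
    """Baseline graph from Bonferroni-adjusted correlation p-values.

    For each of the p(p-1)/2 variable pairs the two-sided p-value of the
    Pearson correlation is computed from the t statistic
    ``r * sqrt((N - 2) / (1 - r^2))`` on N - 2 degrees of freedom, multiplied
    by the number of tested pairs (capped at 1), and an edge is placed where
    the adjusted p-value is below ``level``.
    """
    if not 0 < level <= 1:
        raise ValueError(f"level must be in (0, 1], got {level}")
    corr = pearson_correlation(data)
    n = data.shape[0]
    p = data.shape[1]
    r = corr.to_numpy(dtype=float)
    df = n - 2
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(df / np.maximum(1.0 - r**2, 0.0))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals[np.abs(r) >= 1.0] = 0.0  # perfect correlation: p -> 0
    n_tests = p * (p - 1) // 2
    adjusted = np.minimum(pvals * n_tests, 1.0)
    adj = adjusted < level
    np.fill_diagonal(adj, False)
    adj &= adj.T
    return BinaryGraph(tuple(data.columns), adj)
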