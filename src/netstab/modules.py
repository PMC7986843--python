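"""Module (community) detection by fast-greedy modularity optimization.

Modularity of a partition is

    Q = sum_i (e_ii - s_i^2),

where ``e_ij`` is the fraction of edge endpoints joining module i to module
j (each within-module edge contributes fully to ``e_ii``, each cross edge
half to ``e_ij`` and half to ``e_ji``) and ``s_i = sum_j e_ij`` is module
i's share of edge endpoints.  Q > 0 indicates more within-module edges than
a degree-matched random graph would produce.

Detection uses the agglomerative fast-greedy (CNM) algorithm: starting from
singletons, repeatedly merge the pair of communities with the largest
modularity gain, and cut the resulting dendrogram at the level of maximal Q.
The heavy lifting is delegated to igraph's C implementation; this module
wraps it behind a fixed node-order contract and handles the degenerate
edgeless case, where every node is necessarily its own module.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import BinaryGraph

__all__ = ["ModuleSet", "modularity", "fast_greedy_modules", "read_modules_tsv"]


class ModuleSet:
    """A partition of an ordered node set into disjoint, nonempty modules.

    Module ids are canonical: 1-based, assigned in decreasing module size
    with ties broken by the smallest member index.  Two ModuleSets compare
    equal iff they have the same nodes and induce the same partition.
    """

    __slots__ = ("nodes", "membership", "_index")

    def __init__(self, nodes: Sequence[str], membership: Sequence[int]):
        self.nodes = tuple(str(n) for n in nodes)
        labels = np.asarray(membership, dtype=np.int64)
        if labels.shape != (len(self.nodes),):
            raise ValueError(
                f"membership length {labels.shape} does not match {len(self.nodes)} nodes"
            )
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node labels must be unique")
        self.membership = _canonicalize(labels)
        self._index = {n: i for i, n in enumerate(self.nodes)}

    @classmethod
    def from_modules(
        cls, modules: Iterable[Iterable[str]], nodes: Sequence[str] | None = None
    ) -> "ModuleSet":
        """Build from an explicit list of node-label sets.

        ``nodes`` fixes the canonical node order; if omitted, sorted order of
        all member labels is used.
        """
        mods = [list(m) for m in modules]
        seen: dict[str, int] = {}
        for k, m in enumerate(mods):
            if not m:
                raise ValueError("empty module")
            for n in m:
                n = str(n)
                if n in seen:
                    raise ValueError(f"node {n!r} appears in more than one module")
                seen[n] = k
        if nodes is None:
            nodes = sorted(seen)
        nodes = [str(n) for n in nodes]
        if set(nodes) != set(seen):
            raise ValueError("modules do not partition the given node set")
        return cls(nodes, [seen[n] for n in nodes])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_modules(self) -> int:
        return int(self.membership.max()) + 1 if len(self.nodes) else 0

    @property
    def sizes(self) -> np.ndarray:
        """Module sizes, indexed by canonical module id - 1."""
        return np.bincount(self.membership, minlength=self.n_modules)

    def modules(self) -> list[frozenset]:
        """Modules as frozensets of labels, in canonical id order."""
        out: list[set] = [set() for _ in range(self.n_modules)]
        for n, lab in zip(self.nodes, self.membership):
            out[lab].add(n)
        return [frozenset(m) for m in out]

    def module_id_of(self, node: str) -> int:
        """1-based canonical module id containing ``node``."""
        try:
            return int(self.membership[self._index[str(node)]]) + 1
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def module_of(self, node: str) -> frozenset:
        """The set of labels sharing ``node``'s module."""
        lab = self.module_id_of(node) - 1
        return frozenset(
            n for n, m in zip(self.nodes, self.membership) if m == lab
        )

    def to_frame(self) -> pd.DataFrame:
        """Two columns (variable, module), module ids 1-based by size."""
        return pd.DataFrame(
            {"variable": self.nodes, "module": self.membership + 1}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __eq__(self, other):
        if not isinstance(other, ModuleSet):
            return NotImplemented
        return self.nodes == other.nodes and np.array_equal(
            self.membership, other.membership
        )

    def __hash__(self):
        return hash((self.nodes, self.membership.tobytes()))

    def __repr__(self):
        return f"ModuleSet({self.n_nodes} nodes, {self.n_modules} modules)"


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0-based ids ordered by decreasing size, then first member."""
    uniq, first_pos, inverse, counts = np.unique(
        labels, return_index=True, return_inverse=True, return_counts=True
    )
    order = sorted(range(len(uniq)), key=lambda k: (-counts[k], first_pos[k]))
    rank = np.empty(len(uniq), dtype=np.int64)
    for new_id, old in enumerate(order):
        rank[old] = new_id
    return rank[inverse]


def read_modules_tsv(path) -> ModuleSet:
    df = pd.read_csv(path, sep="\t", dtype={"variable": str})
    return ModuleSet(df["variable"].tolist(), df["module"].to_numpy())


def modularity(graph: BinaryGraph, partition: ModuleSet) -> float:
    """Newman-Girvan modularity Q of a partition of ``graph``'s nodes.

    Isolated nodes carry no edge endpoints and do not contribute.  Raises on
    an edgeless graph, where the endpoint fractions are undefined.
    """
    if graph.n_edges == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    if partition.nodes != graph.nodes:
        if set(partition.nodes) != set(graph.nodes):
            raise ValueError("partition does not cover the graph's node set")
        perm = [partition._index[n] for n in graph.nodes]
        labels = partition.membership[perm]
    else:
        labels = partition.membership
    u = int(labels.max()) + 1
    m = graph.n_edges
    ea = graph.edge_array()
    li, lj = labels[ea[:, 0]], labels[ea[:, 1]]
    # endpoint-count matrix: within edges add 2 to (i,i), cross edges 1 each way
    e = np.zeros((u, u))
    np.add.at(e, (li, lj), 1.0)
    np.add.at(e, (lj, li), 1.0)
    e /= 2.0 * m
    s = e.sum(axis=1)
    return float(np.trace(e) - (s**2).sum())


def fast_greedy_modules(graph: BinaryGraph) -> ModuleSet:
    """Detect modules by greedy agglomerative modularity optimization.

    Returns the partition at the dendrogram cut maximizing Q.  Isolated
    nodes come out as singleton modules; an edgeless graph yields the
    all-singleton partition.  Deterministic: identical graphs give identical
    partitions.
    """
    if graph.n_edges == 0:
        return ModuleSet(graph.nodes, np.arange(graph.n_nodes))
    g = graph.to_igraph()
    dendrogram = g.community_fastgreedy()
    clustering = dendrogram.as_clustering()
    return ModuleSet(graph.nodes, clustering.membership)
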