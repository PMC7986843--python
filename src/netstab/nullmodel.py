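"""Degree-preserving null graphs and the expected stability under no structure.

The observed stability of a thresholded graph is not comparable across edge
densities: a complete graph (one giant module) and an edgeless graph (all
singletons) are both perfectly stable.  To correct for this, the observed
stability is referenced against graphs with the same degree sequence but no
module structure, produced by double-edge-swap randomization.  The expected
null stability is the mean pairwise agreement among the partitions detected
on an ensemble of such randomized graphs.
"""

from __future__ import annotations

import warnings

import numpy as np

from .graph import BinaryGraph
from .modules import fast_greedy_modules
from .stability import _as_rng, partition_agreement

__all__ = ["degree_preserving_randomize", "null_expected_stability"]


def degree_preserving_randomize(graph: BinaryGraph, seed) -> BinaryGraph:
    """Randomize a graph while preserving every node's degree exactly.

    Uses double-edge-swap MCMC: 10 * |E| attempted swaps of edge pairs
    (a,b),(c,d) -> (a,d),(c,b) or (a,c),(b,d), rejecting any swap that would
    create a self-loop or a multi-edge.  Node labels and order are unchanged.
    A graph with fewer than 2 edges is returned unchanged with a warning.
    """
    rng = _as_rng(seed)
    m = graph.n_edges
    if m < 2:
        warnings.warn("graph has fewer than 2 edges; no swap possible")
        return graph
    edges = graph.edge_array()
    edge_set = {(int(i), int(j)) for i, j in edges}
    attempts = 10 * m
    picks = rng.integers(0, m, size=(attempts, 2))
    coins = rng.integers(0, 2, size=attempts)
    for k in range(attempts):
        e1, e2 = picks[k]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if coins[k]:
            u1, v1 = (a, d) if a < d else (d, a)
            u2, v2 = (c, b) if c < b else (b, c)
        else:
            u1, v1 = (a, c) if a < c else (c, a)
            u2, v2 = (b, d) if b < d else (d, b)
        if u1 == v1 or u2 == v2:
            continue
        n1, n2 = (u1, v1), (u2, v2)
        if n1 == n2 or n1 in edge_set or n2 in edge_set:
            continue
        edge_set.discard((int(a), int(b)) if a < b else (int(b), int(a)))
        edge_set.discard((int(c), int(d)) if c < d else (int(d), int(c)))
        edge_set.add((int(n1[0]), int(n1[1])))
        edge_set.add((int(n2[0]), int(n2[1])))
        edges[e1] = n1
        edges[e2] = n2
    p = graph.n_nodes
    adj = np.zeros((p, p), dtype=bool)
    idx = np.array(sorted(edge_set))
    adj[idx[:, 0], idx[:, 1]] = True
    adj |= adj.T
    return BinaryGraph(graph.nodes, adj)


def null_expected_stability(graph: BinaryGraph, m: int, seed) -> float:
    """Expected partition agreement among degree-matched structureless graphs.

    Generates ``m`` degree-preserving randomizations of ``graph``, detects
    modules on each, and returns the mean agreement over all pairs of the m
    resulting partitions (the ordered- and unordered-pair means coincide by
    symmetry).
    """
    if m < 2:
        raise ValueError(f"need m >= 2 null graphs, got {m}")
    rng = _as_rng(seed)
    partitions = [
        fast_greedy_modules(degree_preserving_randomize(graph, rng)) for _ in range(m)
    ]
    total = 0.0
    n_pairs = 0
    for i in range(m):
        for j in range(i + 1, m):
            total += partition_agreement(partitions[i], partitions[j])
            n_pairs += 1
    return total / n_pairs
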