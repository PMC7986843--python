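"""Bootstrap resampling and Jaccard co-membership stability estimates.

Variables (nodes) are fixed; the sampling uncertainty of a correlation
network comes from the subjects, so a bootstrap replicate redraws the N
observations with replacement, re-estimates the correlation matrix, rebuilds
the graph at the same threshold and re-detects modules.  Stability is then
quantified by how consistently each node keeps its module company across
replicates, using the Jaccard coefficient between the node's reference
module and its module in each replicate:

    A(n; M0, Mb) = |M0(n) ∩ Mb(n)| / |M0(n) ∪ Mb(n)|

Averaging over nodes gives the agreement of two partitions; averaging over
replicates gives node-level stability; module- and graph-level stabilities
are means of the node values.  Because the node itself belongs to both
modules, every quantity lies in (0, 1], with 1 meaning perfect agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import json

import numpy as np
import pandas as pd

from .graph import pearson_correlation, threshold_graph
from .modules import ModuleSet, fast_greedy_modules

__all__ = [
    "bootstrap_resample",
    "node_jaccard",
    "partition_agreement",
    "BootstrapEnsemble",
    "bootstrap_modules",
    "node_stability",
    "module_stability",
    "overall_stability",
    "StabilityReport",
    "stability_report",
    "unconditional_observed_stability",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def bootstrap_resample(data: pd.DataFrame, seed) -> pd.DataFrame:
    """Resample the N observations (rows) of ``data`` with replacement.

    Columns and their order are unchanged.  The returned frame keeps the
    original row index values, so row multiplicities remain visible.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = _as_rng(seed)
    n = data.shape[0]
    idx = rng.integers(0, n, size=n)
    return data.iloc[idx]


def _aligned_labels(a: ModuleSet, b: ModuleSet) -> tuple[np.ndarray, np.ndarray]:
    if a.nodes == b.nodes:
        return a.membership, b.membership
    if set(a.nodes) != set(b.nodes):
        raise ValueError("partitions are not over the same node set")
    perm = [b._index[n] for n in a.nodes]
    return a.membership, b.membership[perm]


def _jaccard_table(la: np.ndarray, lb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contingency-based node Jaccards.

    Returns (J, la, lb) where J[i, j] is the Jaccard coefficient between
    module i of the first partition and module j of the second; node k's
    Jaccard is J[la[k], lb[k]].
    """
    ka, kb = int(la.max()) + 1, int(lb.max()) + 1
    counts = np.bincount(la * kb + lb, minlength=ka * kb).reshape(ka, kb)
    sa = counts.sum(axis=1, keepdims=True)
    sb = counts.sum(axis=0, keepdims=True)
    union = sa + sb - counts
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, counts / np.where(union > 0, union, 1), 0.0)
    return jac, la, lb


def _nodewise_jaccard(a: ModuleSet, b: ModuleSet) -> np.ndarray:
    la, lb = _aligned_labels(a, b)
    jac, la, lb = _jaccard_table(la, lb)
    return jac[la, lb]


def node_jaccard(modules_a: ModuleSet, modules_b: ModuleSet, node: str) -> float:
    """Jaccard coefficient between ``node``'s modules in the two partitions."""
    set_a = modules_a.module_of(node)
    set_b = modules_b.module_of(node)
    return len(set_a & set_b) / len(set_a | set_b)


def partition_agreement(modules_a: ModuleSet, modules_b: ModuleSet) -> float:
    """Mean node-wise Jaccard agreement between two partitions.

    Symmetric in its arguments; equals 1 iff the partitions coincide.
    """
    return float(_nodewise_jaccard(modules_a, modules_b).mean())


@dataclass(frozen=True)
class BootstrapEnsemble:
    """A reference partition plus B bootstrap-replicate partitions."""

    reference: ModuleSet
    replicates: tuple
    seed: object = None

    def __post_init__(self):
        if len(self.replicates) < 1:
            raise ValueError("need at least one bootstrap replicate")
        for r in self.replicates:
            if set(r.nodes) != set(self.reference.nodes):
                raise ValueError("all partitions must share the reference node set")
        object.__setattr__(self, "replicates", tuple(self.replicates))

    @property
    def B(self) -> int:
        return len(self.replicates)


def bootstrap_modules(
    data: pd.DataFrame,
    t: float,
    B: int = 100,
    seed=None,
    reference: ModuleSet | None = None,
    max_redraws: int | None = None,
) -> BootstrapEnsemble:
    """Run the bootstrap at a fixed threshold and collect the partitions.

    Each replicate resamples rows, re-estimates the correlation matrix,
    thresholds it at the same ``t`` and detects modules.  A degenerate
    resample (a variable constant across the drawn rows, so its correlations
    are undefined) is discarded with a warning and redrawn, keeping B fixed;
    after ``max_redraws`` (default 10 * B) discards the run aborts.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = _as_rng(seed)
    if reference is None:
        reference = fast_greedy_modules(threshold_graph(pearson_correlation(data), t))
    if max_redraws is None:
        max_redraws = 10 * B
    replicates = []
    redraws = 0
    while len(replicates) < B:
        sample = bootstrap_resample(data, rng)
        try:
            corr = pearson_correlation(sample)
        except ValueError as err:
            redraws += 1
            warnings.warn(f"degenerate bootstrap replicate redrawn: {err}")
            if redraws > max_redraws:
                raise RuntimeError(
                    f"exceeded {max_redraws} redraws of degenerate bootstrap replicates"
                ) from err
            continue
        replicates.append(fast_greedy_modules(threshold_graph(corr, t)))
    return BootstrapEnsemble(reference, tuple(replicates), seed=seed)


def _node_stability_vector(ensemble: BootstrapEnsemble) -> np.ndarray:
    ref = ensemble.reference
    acc = np.zeros(ref.n_nodes)
    for rep in ensemble.replicates:
        acc += _nodewise_jaccard(ref, rep)
    return acc / ensemble.B


def node_stability(ensemble: BootstrapEnsemble, node: str) -> float:
    """Mean Jaccard agreement of ``node``'s module across replicates."""
    ref = ensemble.reference
    if str(node) not in ref._index:
        raise KeyError(f"unknown node {node!r}")
    return float(_node_stability_vector(ensemble)[ref._index[str(node)]])


def module_stability(ensemble: BootstrapEnsemble, module_id: int) -> float:
    """Mean node stability over the members of reference module ``module_id``."""
    ref = ensemble.reference
    if not 1 <= module_id <= ref.n_modules:
        raise ValueError(
            f"module id {module_id} out of range 1..{ref.n_modules}"
        )
    vec = _node_stability_vector(ensemble)
    mask = ref.membership == (module_id - 1)
    return float(vec[mask].mean())


def overall_stability(ensemble: BootstrapEnsemble) -> float:
    """Mean agreement of the replicates with the reference partition.

    Algebraically identical to the mean of the node stabilities over all
    nodes; both routes are computed and cross-checked.
    """
    via_pairs = float(
        np.mean([partition_agreement(ensemble.reference, r) for r in ensemble.replicates])
    )
    via_nodes = float(_node_stability_vector(ensemble).mean())
    assert abs(via_pairs - via_nodes) < 1e-12
    return via_pairs


@dataclass(frozen=True)
class StabilityReport:
    """Node, module and overall stability, conditional on a reference partition."""

    node_stability: dict
    module_stability: dict
    overall: float
    reference: ModuleSet
    B: int

    def __post_init__(self):
        vals = list(self.node_stability.values()) + list(
            self.module_stability.values()
        ) + [self.overall]
        if min(vals) <= 0.0 or max(vals) > 1.0 + 1e-12:
            raise ValueError("stability values must lie in (0, 1]")
        # decomposition identities
        node_vec = np.array([self.node_stability[n] for n in self.reference.nodes])
        if abs(node_vec.mean() - self.overall) > 1e-12:
            raise ValueError("overall stability must equal the mean node stability")
        for mid, val in self.module_stability.items():
            mask = self.reference.membership == (mid - 1)
            if abs(node_vec[mask].mean() - val) > 1e-12:
                raise ValueError(
                    f"module {mid} stability must equal the mean of its members"
                )

    def to_dict(self) -> dict:
        return {
            "node_stability": dict(self.node_stability),
            "module_stability": {str(k): v for k, v in self.module_stability.items()},
            "overall": self.overall,
            "B": self.B,
            "modules": {
                str(i + 1): sorted(m) for i, m in enumerate(self.reference.modules())
            },
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        """Per-node table: variable, module id, node stability, module stability."""
        mids = self.reference.membership + 1
        return pd.DataFrame(
            {
                "variable": self.reference.nodes,
                "module": mids,
                "node_stability": [self.node_stability[n] for n in self.reference.nodes],
                "module_stability": [self.module_stability[int(m)] for m in mids],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def stability_report(ensemble: BootstrapEnsemble) -> StabilityReport:
    """Compute all conditional stability levels for a bootstrap ensemble."""
    ref = ensemble.reference
    vec = _node_stability_vector(ensemble)
    node_map = {n: float(v) for n, v in zip(ref.nodes, vec)}
    module_map = {
        mid: float(vec[ref.membership == (mid - 1)].mean())
        for mid in range(1, ref.n_modules + 1)
    }
    return StabilityReport(
        node_stability=node_map,
        module_stability=module_map,
        overall=float(vec.mean()),
        reference=ref,
        B=ensemble.B,
    )


def unconditional_observed_stability(module_sets: Sequence[ModuleSet]) -> float:
    """Mean pairwise agreement among all partitions, reference included.

    Over the B+1 partitions (the reference plus B replicates) this averages
    the agreement over all ordered pairs i != j, which by symmetry equals the
    unordered-pair mean.  Unlike the conditional overall stability it treats
    every partition symmetrically, which makes it suitable for comparing
    thresholds rather than describing one reference partition.
    """
    sets = list(module_sets)
    if len(sets) < 2:
        raise ValueError("need at least 2 module sets")
    total = 0.0
    n_pairs = 0
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            total += partition_agreement(sets[i], sets[j])
            n_pairs += 1
    return total / n_pairs
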