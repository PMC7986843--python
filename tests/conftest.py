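import numpy as np
import pandas as pd
import pytest

from netstab import BinaryGraph, BlockModelSpec, ModuleSet


@pytest.fixture
def two_triangles():
    """Two disjoint triangles on nodes a..f."""
    return BinaryGraph.from_edges(
        "abcdef",
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
    )


@pytest.fixture
def two_cliques_k4():
    nodes = [f"n{i}" for i in range(8)]
    edges = [(f"n{i}", f"n{j}") for i in range(4) for j in range(i + 1, 4)]
    edges += [(f"n{i}", f"n{j}") for i in range(4, 8) for j in range(i + 1, 8)]
    return BinaryGraph.from_edges(nodes, edges)


@pytest.fixture
def two_block_10():
    """Two dense 5-node blocks joined by a single cross edge."""
    nodes = [f"n{i}" for i in range(10)]
    edges = [(f"n{i}", f"n{j}") for i in range(5) for j in range(i + 1, 5)]
    edges += [(f"n{i}", f"n{j}") for i in range(5, 10) for j in range(i + 1, 10)]
    edges.append(("n0", "n5"))
    return BinaryGraph.from_edges(nodes, edges)


@pytest.fixture
def pair_partitions():
    """The worked 4-node pair: {{1,2},{3,4}} vs {{1,2,3},{4}}."""
    nodes = ["1", "2", "3", "4"]
    a = ModuleSet.from_modules([{"1", "2"}, {"3", "4"}], nodes=nodes)
    b = ModuleSet.from_modules([{"1", "2", "3"}, {"4"}], nodes=nodes)
    return a, b


@pytest.fixture
def small_block_spec():
    return BlockModelSpec(p=12, n_modules=3, alpha=0.7, beta=0.1, N=40)


@pytest.fixture
def toy_data():
    """20 x 12 Gaussian draws from a 3-block correlation model."""
    from netstab import block_diagonal_correlation, sample_gaussian

    spec = BlockModelSpec(p=12, n_modules=3, alpha=0.8, beta=0.05, N=20)
    return sample_gaussian(block_diagonal_correlation(spec), spec.N, seed=42)


def random_partition(rng, nodes, max_modules=4) -> ModuleSet:
    labels = rng.integers(0, max_modules, size=len(nodes))
    return ModuleSet(nodes, labels)
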