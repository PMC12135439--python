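import numpy as np
import pytest

from grnactive.datasets import ExpressionDataset
from grnactive.graphs import DirectedGraph
from grnactive.posterior import PosteriorSampleSet


@pytest.fixture
def chain3() -> DirectedGraph:
    """0 -> 1 -> 2: a chain whose essential graph is fully undirected."""
    return DirectedGraph(3, frozenset({(0, 1), (1, 2)}))


@pytest.fixture
def collider3() -> DirectedGraph:
    """0 -> 2 <- 1: a v-structure, fully compelled."""
    return DirectedGraph(3, frozenset({(0, 2), (1, 2)}))


@pytest.fixture
def chain_data() -> ExpressionDataset:
    """600 observational samples from x0 -> x1 -> x2 (strong linear effects)."""
    rng = np.random.default_rng(42)
    x0 = rng.normal(size=600)
    x1 = 2.0 * x0 + rng.normal(size=600)
    x2 = -1.5 * x1 + rng.normal(size=600)
    return ExpressionDataset(np.column_stack([x0, x1, x2]))


@pytest.fixture
def collider_data() -> ExpressionDataset:
    """1000 observational samples from x0 -> x2 <- x1."""
    rng = np.random.default_rng(7)
    x0 = rng.normal(size=1000)
    x1 = rng.normal(size=1000)
    x2 = 1.5 * x0 - 1.5 * x1 + rng.normal(size=1000)
    return ExpressionDataset(np.column_stack([x0, x1, x2]))


def sample_set_from(graphs, weights=None, group_ids=None) -> PosteriorSampleSet:
    return PosteriorSampleSet.from_graphs(list(graphs), weights, group_ids)


@pytest.fixture
def random_sample_set() -> PosteriorSampleSet:
    """60 random 6-node DAG samples in 3 groups, non-uniform weights."""
    from oracles import random_dag
    rng = np.random.default_rng(3)
    graphs = [random_dag(6, 0.4, rng) for _ in range(60)]
    w = rng.random(60) + 0.1
    gid = np.repeat([0, 1, 2], 20)
    return PosteriorSampleSet.from_graphs(graphs, w, gid)
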