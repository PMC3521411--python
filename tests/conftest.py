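import numpy as np
import pytest

from multiwalk import (
    GeneMultigraph,
    SimilarityMatrix,
    WeightedNetwork,
    toy_chn,
    toy_merged_matrix_rounded,
    toy_multigraph,
)


@pytest.fixture
def toy_mg():
    return toy_multigraph()


@pytest.fixture
def toy_matrix():
    return toy_merged_matrix_rounded()


@pytest.fixture
def toy_het():
    return toy_chn()


def random_network(rng: np.random.Generator, n: int, p: float = 0.4) -> WeightedNetwork:
    """Random connected-enough weighted network for property tests.

    Builds a ring (so no node is isolated) plus Bernoulli(p) chords with
    uniform weights in (0, 2].
    """
    nodes = [f"n{i:03d}" for i in range(n)]
    edges = []
    for i in range(n):
        j = (i + 1) % n
        a, b = sorted((nodes[i], nodes[j]))
        edges.append((a, b, float(rng.uniform(0.1, 2.0))))
    seen = {tuple(sorted((a, b))) for a, b, _ in edges}
    for i in range(n):
        for j in range(i + 1, n):
            key = (nodes[i], nodes[j])
            if key not in seen and rng.random() < p:
                seen.add(key)
                edges.append((nodes[i], nodes[j], float(rng.uniform(0.1, 2.0))))
    return WeightedNetwork.from_edges(edges, node_ids=nodes)


def random_multigraph(
    rng: np.random.Generator, n: int = 12, n_layers: int = 3
) -> GeneMultigraph:
    layers = tuple(random_network(rng, n) for _ in range(n_layers))
    return GeneMultigraph(layers=layers)


def random_similarity(rng: np.random.Generator, n: int) -> SimilarityMatrix:
    raw = rng.uniform(0, 1, size=(n, n))
    vals = (raw + raw.T) / 2
    np.fill_diagonal(vals, 0.0)
    ids = tuple(f"s{i:02d}" for i in range(n))
    return SimilarityMatrix(node_ids=ids, values=vals)
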