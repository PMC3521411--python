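"""Graph and matrix primitives.

Similarity matrices, weighted undirected networks, row-stochastic transition
matrices, KNN-graph construction from a similarity matrix, and
annotation-overlap functional similarity between genes.

The transition matrix of a weighted undirected network is the degree
normalisation ``M[i, j] = A[i, j] / d(i)`` where ``d(i)`` is the weighted
degree of node *i* (column sum of the symmetric adjacency ``A``), so every
row sums to one and a random walker at *i* picks an incident edge with
probability proportional to its weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-6
_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric matrix of pairwise similarity scores (>= 0).

    The diagonal is ignored by every consumer: self-similarity never
    creates an edge.
    """

    node_ids: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        n = len(self.node_ids)
        if vals.shape != (n, n):
            raise ValidationError(
                f"similarity matrix shape {vals.shape} does not match "
                f"{n} node identifiers"
            )
        if len(set(self.node_ids)) != n:
            raise ValidationError("duplicate node identifiers in similarity matrix")
        if not np.allclose(vals, vals.T, atol=_SYMMETRY_TOL, rtol=0):
            worst = float(np.abs(vals - vals.T).max())
            raise ValidationError(
                f"similarity matrix is asymmetric (max |S - S^T| = {worst:.3g})"
            )

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index(self, node: str) -> int:
        return self.node_ids.index(node)


@dataclass(frozen=True)
class WeightedNetwork:
    """Undirected weighted graph for one data source.

    No self-loops, strictly positive weights, no duplicate pairs, and every
    retained node has at least one incident edge (isolated nodes cannot carry
    a row of a stochastic matrix and must be dropped by the caller).
    """

    node_ids: Tuple[str, ...]
    graph: nx.Graph = field(compare=False)

    def __post_init__(self):
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        known = set(self.node_ids)
        if len(known) != len(self.node_ids):
            raise ValidationError("duplicate node identifiers in network")
        for a, b, data in self.graph.edges(data=True):
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            w = data.get("weight", 1.0)
            if not w > 0:
                raise ValidationError(f"non-positive weight {w} on edge ({a!r}, {b!r})")
            if a not in known or b not in known:
                raise ValidationError(f"edge ({a!r}, {b!r}) uses unknown node")
        for node in self.node_ids:
            if self.graph.degree(node) == 0:
                raise ValidationError(
                    f"node {node!r} has no incident edge; drop it at construction"
                )

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str, float]],
        node_ids: Sequence[str] | None = None,
    ) -> "WeightedNetwork":
        """Build from ``(a, b, weight)`` triples; duplicate pairs are rejected.

        Node order defaults to first appearance in the edge list.
        """
        g = nx.Graph()
        order: List[str] = []
        seen: Set[str] = set()
        for a, b, w in edges:
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            if g.has_edge(a, b):
                raise ValidationError(f"duplicate edge ({a!r}, {b!r})")
            if not float(w) > 0:
                raise ValidationError(f"non-positive weight {w} on edge ({a!r}, {b!r})")
            g.add_edge(a, b, weight=float(w))
            for node in (a, b):
                if node not in seen:
                    seen.add(node)
                    order.append(node)
        if node_ids is not None:
            missing = seen - set(node_ids)
            if missing:
                raise ValidationError(f"edges reference nodes outside node_ids: {sorted(missing)}")
            order = [n for n in node_ids if n in seen]
        if not order:
            raise ValidationError("network has no edges")
        g.add_nodes_from(order)
        return cls(node_ids=tuple(order), graph=g)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def has_node(self, node: str) -> bool:
        return node in self.graph and self.graph.degree(node) > 0

    def edges(self) -> List[Tuple[str, str, float]]:
        """Edges as sorted triples (a < b), deterministic order."""
        out = []
        for a, b, data in self.graph.edges(data=True):
            x, y = sorted((a, b))
            out.append((x, y, float(data.get("weight", 1.0))))
        return sorted(out)

    def adjacency(self, node_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = tuple(node_ids) if node_ids is not None else self.node_ids
        return nx.to_numpy_array(self.graph, nodelist=ids, weight="weight")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix: entry (i, j) is P(move from i to j), zero diagonal."""

    node_ids: Tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        n = len(self.node_ids)
        if probs.shape != (n, n):
            raise ValidationError("transition matrix shape mismatch")
        if probs.min() < -_ROW_SUM_TOL or probs.max() > 1 + _ROW_SUM_TOL:
            raise ValidationError("transition probabilities outside [0, 1]")
        rows = probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_ROW_SUM_TOL, rtol=0):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValidationError(
                f"row {self.node_ids[bad]!r} sums to {rows[bad]:.12f}, not 1"
            )
        if np.any(np.diag(probs) != 0):
            raise ValidationError("transition matrix has a nonzero diagonal entry")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index(self, node: str) -> int:
        return self.node_ids.index(node)


@dataclass(frozen=True)
class AnnotationTable:
    """Mapping gene identifier -> set of annotation-term identifiers."""

    terms: Mapping[str, FrozenSet[str]]

    def __post_init__(self):
        object.__setattr__(
            self,
            "terms",
            {g: frozenset(t) for g, t in self.terms.items()},
        )

    @property
    def genes(self) -> List[str]:
        return sorted(self.terms)


def build_knn_graph(sim: SimilarityMatrix, k: int) -> WeightedNetwork:
    """Connect each node to its ``k`` most similar partners.

    The edge set is the union over all nodes, so degrees may exceed ``k``
    (a node chosen by many partners keeps every such edge). Edge weight is
    the similarity score. Self-similarity and non-positive similarities
    never create edges; ties at the k-th similarity are broken by ascending
    node identifier so the output is deterministic.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    n = sim.n
    if n < 2:
        raise ValidationError("similarity matrix needs at least 2 nodes")
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the node count {n}")
    ids = sim.node_ids
    edges: Dict[Tuple[str, str], float] = {}
    for i, node in enumerate(ids):
        partners = [
            (ids[j], float(sim.values[i, j]))
            for j in range(n)
            if j != i and sim.values[i, j] > 0
        ]
        partners.sort(key=lambda p: (-p[1], p[0]))
        for other, score in partners[:k]:
            key = tuple(sorted((node, other)))
            edges.setdefault(key, score)
    if not edges:
        raise ValidationError("no positive similarities: KNN graph would be empty")
    triples = [(a, b, w) for (a, b), w in edges.items()]
    return WeightedNetwork.from_edges(triples, node_ids=ids)


def transition_from_network(net: WeightedNetwork) -> TransitionMatrix:
    """Degree-normalised transition matrix of one weighted network."""
    A = net.adjacency()
    d = A.sum(axis=1)
    if np.any(d <= 0):
        bad = net.node_ids[int(np.argmin(d))]
        raise ValidationError(
            f"node {bad!r} is isolated; drop it when constructing the network"
        )
    M = A / d[:, None]
    return TransitionMatrix(node_ids=net.node_ids, probs=M)


def annotation_overlap_similarity(
    ann: AnnotationTable, mode: str = "count"
) -> SimilarityMatrix:
    """Pairwise gene functional similarity from shared annotation terms.

    ``count`` mode scores a pair by the size of the intersection of their
    term sets; ``jaccard`` divides by the union size (0 when both sets are
    empty). Output is symmetric with zero diagonal.
    """
    if mode not in ("count", "jaccard"):
        raise ValidationError(f"mode must be 'count' or 'jaccard', got {mode!r}")
    genes = ann.genes
    if len(genes) < 2:
        raise ValidationError("annotation table needs at least 2 genes")
    n = len(genes)
    vals = np.zeros((n, n))
    for i in range(n):
        ti = ann.terms[genes[i]]
        for j in range(i + 1, n):
            tj = ann.terms[genes[j]]
            inter = len(ti & tj)
            if mode == "count":
                s = float(inter)
            else:
                union = len(ti | tj)
                s = inter / union if union else 0.0
            vals[i, j] = vals[j, i] = s
    return SimilarityMatrix(node_ids=tuple(genes), values=vals)
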