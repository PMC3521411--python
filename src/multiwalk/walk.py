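"""Random walk with restart (RWR) and its multigraph extension (RWRM).

A multigraph gene network stacks several undirected networks (layers) over a
shared node universe: between two genes there may be one parallel edge per
data source. A walker at gene *i* first picks one of the ``N_i`` layers that
contain *i* (uniformly by default) and then takes an ordinary degree-weighted
step inside that layer, so the merged transition probability is the
expectation of the per-layer transition probabilities:

    M[i, j] = sum_k q_k * M_k[i, j],   q_k = 1 / N_i over layers containing i.

The walk itself iterates ``p <- (1 - gamma) * M^T p + gamma * p0`` until the
L1 change between successive iterates falls below tolerance. With a
row-stochastic ``M`` this conserves total probability at every step, and the
update is a contraction with factor (1 - gamma), so convergence is geometric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .exceptions import ConvergenceError, ValidationError
from .graph_core import TransitionMatrix, WeightedNetwork, transition_from_network

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkConfig:
    """Restart probability, convergence tolerance and iteration cap."""

    gamma: float = 0.7
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self):
        if not (0 < self.gamma <= 1):
            raise ValidationError(f"gamma must be in (0, 1], got {self.gamma}")
        if not self.tol > 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be positive")


@dataclass(frozen=True)
class InitialDistribution:
    """Probability vector over an ordered node set; sums to one."""

    node_ids: Tuple[str, ...]
    p0: np.ndarray

    def __post_init__(self):
        p0 = np.asarray(self.p0, dtype=float)
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        if p0.shape != (len(self.node_ids),):
            raise ValidationError("initial vector length does not match node count")
        if p0.min() < 0:
            raise ValidationError("initial vector has a negative entry")
        if abs(p0.sum() - 1.0) > 1e-9:
            raise ValidationError(f"initial vector sums to {p0.sum()}, not 1")

    @classmethod
    def uniform_over(
        cls, node_ids: Sequence[str], seeds: Iterable[str]
    ) -> "InitialDistribution":
        """Equal probability on every seed node, total mass one."""
        ids = tuple(node_ids)
        seed_set = set(seeds)
        if not seed_set:
            raise ValidationError("seed set is empty")
        missing = seed_set - set(ids)
        if missing:
            raise ValidationError(f"seed nodes not in universe: {sorted(missing)}")
        p0 = np.zeros(len(ids))
        for s in seed_set:
            p0[ids.index(s)] = 1.0 / len(seed_set)
        return cls(node_ids=ids, p0=p0)


@dataclass(frozen=True)
class StationaryResult:
    """Converged probability vector with convergence diagnostics.

    ``residual_history`` holds the L1 change at every iteration and
    ``mass_history`` the total probability after every iteration, so callers
    can verify conservation and the geometric contraction directly.
    """

    node_ids: Tuple[str, ...]
    p: np.ndarray
    iterations: int
    residual: float
    residual_history: Tuple[float, ...] = ()
    mass_history: Tuple[float, ...] = ()

    def score(self, node: str) -> float:
        return float(self.p[self.node_ids.index(node)])


@dataclass(frozen=True)
class GeneMultigraph:
    """Ordered layers of weighted networks over a shared node universe.

    Every universe node must have at least one incident edge in at least one
    layer (``N_i >= 1``); an edgeless node would contribute an all-zero,
    non-stochastic row to the merged matrix. ``layer_weights``, when given,
    replace the uniform 1/N_i layer choice; they must sum to one over the
    layers containing each node.
    """

    layers: Tuple[WeightedNetwork, ...]
    universe: Tuple[str, ...] = ()
    layer_weights: Tuple[float, ...] | None = None

    def __post_init__(self):
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if not layers:
            raise ValidationError("multigraph needs at least one layer")
        present: Set[str] = set()
        for layer in layers:
            present.update(layer.node_ids)
        if self.universe:
            universe = tuple(self.universe)
            extra = present - set(universe)
            if extra:
                raise ValidationError(f"layer nodes outside universe: {sorted(extra)}")
            orphan = set(universe) - present
            if orphan:
                raise ValidationError(
                    f"universe nodes absent from every layer: {sorted(orphan)}"
                )
        else:
            universe = tuple(sorted(present))
        object.__setattr__(self, "universe", universe)
        if self.layer_weights is not None:
            w = tuple(float(x) for x in self.layer_weights)
            if len(w) != len(layers):
                raise ValidationError("one layer weight per layer required")
            object.__setattr__(self, "layer_weights", w)

    @property
    def n(self) -> int:
        return len(self.universe)

    def layer_counts(self) -> Dict[str, int]:
        """N_i: number of layers in which each node has an incident edge."""
        return {
            node: sum(1 for layer in self.layers if layer.has_node(node))
            for node in self.universe
        }


def merge_transition(mg: GeneMultigraph) -> TransitionMatrix:
    """Expected transition matrix over layers (uniform layer choice by default)."""
    ids = mg.universe
    n = len(ids)
    counts = mg.layer_counts()
    merged = np.zeros((n, n))
    membership = [
        np.array([layer.has_node(node) for node in ids]) for layer in mg.layers
    ]
    if mg.layer_weights is not None:
        per_node = np.zeros(n)
        for mask, w in zip(membership, mg.layer_weights):
            per_node += mask * w
        bad = [
            ids[i]
            for i in range(n)
            if membership_any(membership, i) and abs(per_node[i] - 1.0) > 1e-9
        ]
        if bad:
            raise ValidationError(
                f"custom layer weights do not sum to 1 for nodes: {bad}"
            )
    for layer, mask, k in zip(mg.layers, membership, range(len(mg.layers))):
        sub = transition_from_network(layer)
        # scatter the layer's rows/columns into universe coordinates
        idx = np.array([ids.index(x) for x in sub.node_ids])
        if mg.layer_weights is not None:
            q = np.full(len(idx), mg.layer_weights[k])
        else:
            q = np.array([1.0 / counts[x] for x in sub.node_ids])
        merged[np.ix_(idx, idx)] += q[:, None] * sub.probs
    return TransitionMatrix(node_ids=ids, probs=merged)


def membership_any(membership: List[np.ndarray], i: int) -> bool:
    return any(mask[i] for mask in membership)


def rwr(
    M: TransitionMatrix,
    p0: InitialDistribution,
    cfg: WalkConfig = WalkConfig(),
) -> StationaryResult:
    """Iterate the restart walk to its stationary distribution.

    Raises :class:`ConvergenceError` (reporting the final residual) if the
    L1 change between iterates has not dropped below ``cfg.tol`` within
    ``cfg.max_iter`` steps.
    """
    if M.node_ids != p0.node_ids:
        raise ValidationError("transition matrix and initial vector node order differ")
    MT = M.probs.T.copy()
    restart = cfg.gamma * p0.p0
    p = p0.p0.copy()
    residuals: List[float] = []
    masses: List[float] = []
    for it in range(1, cfg.max_iter + 1):
        p_next = (1.0 - cfg.gamma) * (MT @ p) + restart
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        residuals.append(residual)
        masses.append(float(p.sum()))
        if residual <= cfg.tol:
            return StationaryResult(
                node_ids=M.node_ids,
                p=p,
                iterations=it,
                residual=residual,
                residual_history=tuple(residuals),
                mass_history=tuple(masses),
            )
    raise ConvergenceError(
        f"no convergence after {cfg.max_iter} iterations (residual {residual:.3e})",
        residual=residual,
        iterations=cfg.max_iter,
    )


def rank_candidates(
    result: StationaryResult, candidates: Iterable[str]
) -> List[Tuple[str, float]]:
    """Sort candidates by descending stationary probability, ties by identifier."""
    cand = sorted(set(candidates))
    missing = [c for c in cand if c not in result.node_ids]
    if missing:
        raise ValidationError(f"candidates not in universe: {missing}")
    scored = [(c, result.score(c)) for c in cand]
    scored.sort(key=lambda cs: (-cs[1], cs[0]))
    return scored


def prioritize(
    mg: GeneMultigraph,
    seeds: Set[str],
    candidates: Set[str],
    cfg: WalkConfig = WalkConfig(),
    M: TransitionMatrix | None = None,
) -> List[Tuple[str, float]]:
    """Rank candidate genes by proximity to the seed genes on the merged network.

    ``M`` may be supplied to reuse a precomputed merged transition matrix
    (the merge does not depend on seeds).
    """
    if not seeds:
        raise ValidationError("seed set is empty")
    if seeds & candidates:
        raise ValidationError(
            f"seeds and candidates overlap: {sorted(seeds & candidates)}"
        )
    if M is None:
        M = merge_transition(mg)
    p0 = InitialDistribution.uniform_over(M.node_ids, seeds)
    result = rwr(M, p0, cfg)
    return rank_candidates(result, candidates)
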