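"""Toy fixtures and a seeded synthetic benchmark generator.

The toy objects encode the small worked examples used throughout the test
suite: a three-layer multigraph over five genes and a heterogeneous network
adding four phenotypes and three gene-phenotype associations. Their merged
transition values are known in exact fractions (e.g. p(g1->g2) = 3/4,
p(g2->g3) = 4/9).

``generate_benchmark`` emulates the structure the walk methods exploit:
similar phenotypes are caused by mutations in functionally related genes.
It plants gene modules shared across layers, a block-structured phenotype
similarity aligned with the modules, gene-phenotype associations within
modules, one disease per module, and gene positions laid out so that
linkage intervals mix module and background genes. Everything is drawn from
independent RNG streams spawned from one seed, so adding an artifact never
perturbs the draws of another and outputs are byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .chn import AssociationTable, HeterogeneousNetwork
from .exceptions import ValidationError
from .graph_core import SimilarityMatrix, TransitionMatrix, WeightedNetwork
from .evaluation import DiseaseGeneSets, GenePosition, GenePositionTable
from .walk import GeneMultigraph

logger = logging.getLogger(__name__)

TOY_GENES = ("g1", "g2", "g3", "g4", "g5")
TOY_PHENOTYPES = ("Ph1", "Ph2", "Ph3", "Ph4")


def toy_multigraph() -> GeneMultigraph:
    """Three-layer unit-weight multigraph over genes g1..g5.

    Layer memberships are N = (2, 3, 3, 2, 1) for g1..g5, giving the merged
    transition values p(g1->g2) = 1/2*1/2 + 1/2*1 = 0.75 and
    p(g2->g3) = 1/3*(1/2 + 1/3 + 1/2) = 4/9.
    """
    layer1 = WeightedNetwork.from_edges(
        [("g1", "g2", 1), ("g1", "g3", 1), ("g2", "g3", 1), ("g3", "g5", 1)]
    )
    layer2 = WeightedNetwork.from_edges(
        [("g1", "g2", 1), ("g2", "g3", 1), ("g2", "g4", 1)]
    )
    layer3 = WeightedNetwork.from_edges([("g2", "g3", 1), ("g2", "g4", 1)])
    return GeneMultigraph(layers=(layer1, layer2, layer3), universe=TOY_GENES)


def toy_merged_matrix_rounded() -> TransitionMatrix:
    """The 5x5 merged transition matrix of the worked example, at 2 dp.

    This is the display-rounded matrix the small ranking example runs on.
    Its sparsity pattern differs from ``merge_transition(toy_multigraph())``
    because the full edge lists behind it are not recoverable from the
    inline formulas alone; rows sum to one at the printed precision.
    """
    probs = np.array(
        [
            [0.00, 0.75, 0.25, 0.00, 0.00],
            [0.28, 0.00, 0.44, 0.28, 0.00],
            [0.08, 0.58, 0.00, 0.08, 0.26],
            [0.00, 0.00, 0.50, 0.00, 0.50],
            [0.00, 0.33, 0.50, 0.17, 0.00],
        ]
    )
    return TransitionMatrix(node_ids=TOY_GENES, probs=probs)


def toy_phenotype_network() -> WeightedNetwork:
    """Four-phenotype unit-weight network used by the heterogeneous toy."""
    return WeightedNetwork.from_edges(
        [("Ph1", "Ph2", 1), ("Ph2", "Ph3", 1), ("Ph2", "Ph4", 1), ("Ph3", "Ph4", 1)],
        node_ids=TOY_PHENOTYPES,
    )


def toy_chn(lam: float = 0.5, eta: float = 0.5) -> HeterogeneousNetwork:
    """Toy heterogeneous network: toy multigraph + 4 phenotypes + 3 associations.

    Bridging nodes are exactly {g2, g3, Ph2, Ph3}. With the default
    lambda = 0.5 the assembled block matrix has p(g2->g3) = 4/9 * 1/2 = 0.22,
    p(g2->Ph2) = p(g2->Ph3) = 0.25 and p(g3->Ph3) = 0.5, while the internal
    gene g1 keeps its merged row (p(g1->g2) = 0.75).
    """
    assoc = AssociationTable.from_pairs(
        [("g2", "Ph2"), ("g2", "Ph3"), ("g3", "Ph3")],
        gene_ids=TOY_GENES,
        phenotype_ids=TOY_PHENOTYPES,
    )
    return HeterogeneousNetwork(
        genes=toy_multigraph(),
        phenotypes=toy_phenotype_network(),
        associations=assoc,
        lam=lam,
        eta=eta,
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module benchmark.

    Defaults are the easy regime: dense within-module edges (0.9) against a
    sparse background (0.01) across three layers, module size 10 — a strong,
    clean signal under which the held-out disease gene should almost always
    rank first. Setting ``background_edge_prob`` equal to
    ``within_module_edge_prob`` removes the planted signal entirely (the
    null regime, where ranking is uninformative and AUC sits near 0.5).
    """

    n_genes: int = 200
    n_layers: int = 3
    n_phenotypes: int = 8
    n_modules: int = 4
    module_size: int = 10
    within_module_edge_prob: float = 0.9
    background_edge_prob: float = 0.01
    phenotype_within_similarity: float = 0.8
    phenotype_background_similarity: float = 0.1
    pgr_per_module: int = 3
    rng_seed: int = 0
    n_chromosomes: int = 2

    def __post_init__(self):
        for name in (
            "within_module_edge_prob",
            "background_edge_prob",
            "phenotype_within_similarity",
            "phenotype_background_similarity",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_genes",
            "n_layers",
            "n_phenotypes",
            "n_modules",
            "module_size",
            "pgr_per_module",
            "n_chromosomes",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.module_size * self.n_modules > self.n_genes:
            raise ValidationError(
                f"{self.n_modules} modules of size {self.module_size} exceed "
                f"{self.n_genes} genes"
            )
        if self.pgr_per_module > self.module_size:
            raise ValidationError("pgr_per_module cannot exceed module_size")


Benchmark = Tuple[
    GeneMultigraph, SimilarityMatrix, AssociationTable, DiseaseGeneSets, GenePositionTable
]


def generate_benchmark(spec: SyntheticSpec) -> Benchmark:
    """Generate a fully reproducible planted-module benchmark.

    Returns the gene multigraph, the phenotype similarity matrix, the
    gene-phenotype association table, one disease gene set per module, and a
    gene position table. One child RNG stream per artifact is spawned from
    ``spec.rng_seed``.
    """
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    phens = [f"ph{i:03d}" for i in range(spec.n_phenotypes)]
    module_of_gene: Dict[str, int] = {}
    modules: List[List[str]] = []
    for m in range(spec.n_modules):
        block = genes[m * spec.module_size : (m + 1) * spec.module_size]
        modules.append(block)
        for g in block:
            module_of_gene[g] = m

    streams = np.random.SeedSequence(spec.rng_seed).spawn(spec.n_layers + 3)
    layer_rngs = [np.random.default_rng(s) for s in streams[: spec.n_layers]]
    phen_rng = np.random.default_rng(streams[spec.n_layers])
    pgr_rng = np.random.default_rng(streams[spec.n_layers + 1])
    pos_rng = np.random.default_rng(streams[spec.n_layers + 2])

    n = spec.n_genes
    same_module = np.zeros((n, n), dtype=bool)
    for block in modules:
        lo = genes.index(block[0])
        hi = lo + len(block)
        same_module[lo:hi, lo:hi] = True
    np.fill_diagonal(same_module, False)
    iu = np.triu_indices(n, k=1)
    p_edge = np.where(
        same_module[iu], spec.within_module_edge_prob, spec.background_edge_prob
    )

    layers: List[WeightedNetwork] = []
    edge_matrix = np.zeros((spec.n_layers, len(p_edge)), dtype=bool)
    for k, rng in enumerate(layer_rngs):
        edge_matrix[k] = rng.random(len(p_edge)) < p_edge
    # a gene with no edge in any layer cannot enter the multigraph: attach it
    # to its successor in layer 0 (deterministic, rare outside the null regime)
    covered = np.zeros(n, dtype=bool)
    for k in range(spec.n_layers):
        for e, (i, j) in enumerate(zip(*iu)):
            if edge_matrix[k, e]:
                covered[i] = covered[j] = True
    pair_index = {(i, j): e for e, (i, j) in enumerate(zip(*iu))}
    for i in np.nonzero(~covered)[0]:
        j = (i + 1) % n
        a, b = min(i, j), max(i, j)
        logger.warning("gene %s isolated in all layers; adding rescue edge", genes[i])
        edge_matrix[0, pair_index[(a, b)]] = True
    for k in range(spec.n_layers):
        triples = [
            (genes[i], genes[j], 1.0)
            for e, (i, j) in enumerate(zip(*iu))
            if edge_matrix[k, e]
        ]
        if not triples:
            raise ValidationError(f"layer {k} drew no edges; raise the edge probabilities")
        layers.append(WeightedNetwork.from_edges(triples, node_ids=genes))
    mg = GeneMultigraph(layers=tuple(layers), universe=tuple(genes))

    module_of_phen = {p: i % spec.n_modules for i, p in enumerate(phens)}
    ps = np.full((spec.n_phenotypes, spec.n_phenotypes), spec.phenotype_background_similarity)
    for i, a in enumerate(phens):
        for j, b in enumerate(phens):
            if i != j and module_of_phen[a] == module_of_phen[b]:
                ps[i, j] = spec.phenotype_within_similarity
    noise = phen_rng.uniform(0, 0.05, size=ps.shape)
    ps = np.clip(ps + (noise + noise.T) / 2, 0, None)
    np.fill_diagonal(ps, 0.0)
    phen_sim = SimilarityMatrix(node_ids=tuple(phens), values=ps)

    pairs = []
    for p in phens:
        block = modules[module_of_phen[p]]
        chosen = pgr_rng.choice(len(block), size=spec.pgr_per_module, replace=False)
        pairs.extend((block[c], p) for c in sorted(chosen))
    pgrs = AssociationTable.from_pairs(
        sorted(set(pairs)), gene_ids=tuple(genes), phenotype_ids=tuple(phens)
    )

    disease_sets = DiseaseGeneSets(
        {f"disease{m:02d}": frozenset(block) for m, block in enumerate(modules)}
    )

    order = pos_rng.permutation(n)
    positions: Dict[str, GenePosition] = {}
    per_chrom = -(-n // spec.n_chromosomes)  # ceil
    for slot, gi in enumerate(order):
        chrom = f"chr{slot // per_chrom + 1}"
        offset = slot % per_chrom
        start = offset * 1000 + 1
        positions[genes[gi]] = GenePosition(chrom=chrom, start=start, end=start + 500)
    pos_table = GenePositionTable(positions=positions)

    return mg, phen_sim, pgrs, disease_sets, pos_table
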