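"""Complex heterogeneous network: gene multigraph + phenotype network walk.

The two subnetworks are joined by a binary gene-phenotype association matrix
``B``. Genes or phenotypes with at least one association are *bridging*
nodes; the rest are *internal*. A walker at a bridging node jumps to the
other subnetwork with probability ``lambda`` (spread uniformly over its
associations) and stays home with probability ``1 - lambda``, so its
intra-subnetwork row is scaled by ``1 - lambda``. Internal rows are
unchanged. The block transition matrix is

    M = [ M_G   M_GP ]
        [ M_PG  M_P  ]

with ``M_GP[i, j] = lambda * B[i, j] / row_sum_i(B)`` for bridging genes and
``M_PG[i, j] = lambda * B[j, i] / col_sum_i(B)`` for bridging phenotypes.
The restart vector splits its mass ``(1 - eta)`` to gene seeds and ``eta``
to phenotype seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

import numpy as np

from .exceptions import ValidationError
from .graph_core import TransitionMatrix, WeightedNetwork, transition_from_network
from .walk import (
    GeneMultigraph,
    InitialDistribution,
    StationaryResult,
    WalkConfig,
    merge_transition,
    rwr,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationTable:
    """Binary gene-phenotype incidence matrix (rows genes, columns phenotypes)."""

    gene_ids: Tuple[str, ...]
    phenotype_ids: Tuple[str, ...]
    incidence: np.ndarray

    def __post_init__(self):
        B = np.asarray(self.incidence, dtype=float)
        object.__setattr__(self, "incidence", B)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "phenotype_ids", tuple(self.phenotype_ids))
        if B.shape != (len(self.gene_ids), len(self.phenotype_ids)):
            raise ValidationError("incidence matrix shape mismatch")
        if not np.all(np.isin(B, (0.0, 1.0))):
            raise ValidationError("incidence entries must be 0 or 1")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.phenotype_ids)) != len(self.phenotype_ids):
            raise ValidationError("duplicate phenotype identifiers")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[Tuple[str, str]],
        gene_ids: Sequence[str] | None = None,
        phenotype_ids: Sequence[str] | None = None,
    ) -> "AssociationTable":
        pair_list = list(pairs)
        if len(set(pair_list)) != len(pair_list):
            dup = sorted({p for p in pair_list if pair_list.count(p) > 1})
            raise ValidationError(f"duplicate gene-phenotype pairs: {dup}")
        genes = tuple(gene_ids) if gene_ids is not None else tuple(
            sorted({g for g, _ in pair_list})
        )
        phens = tuple(phenotype_ids) if phenotype_ids is not None else tuple(
            sorted({p for _, p in pair_list})
        )
        B = np.zeros((len(genes), len(phens)))
        gi = {g: i for i, g in enumerate(genes)}
        pi = {p: i for i, p in enumerate(phens)}
        for g, p in pair_list:
            if g not in gi:
                raise ValidationError(f"association gene {g!r} not in gene_ids")
            if p not in pi:
                raise ValidationError(f"association phenotype {p!r} not in phenotype_ids")
            B[gi[g], pi[p]] = 1.0
        return cls(gene_ids=genes, phenotype_ids=phens, incidence=B)

    def pairs(self) -> List[Tuple[str, str]]:
        """Associations as sorted (gene, phenotype) pairs."""
        gi, pi = np.nonzero(self.incidence)
        return sorted(
            (self.gene_ids[i], self.phenotype_ids[j]) for i, j in zip(gi, pi)
        )

    def without(self, gene: str, phenotype: str) -> "AssociationTable":
        """Copy with one association removed (leave-one-out helper)."""
        B = self.incidence.copy()
        i = self.gene_ids.index(gene)
        j = self.phenotype_ids.index(phenotype)
        if B[i, j] != 1:
            raise ValidationError(f"no association ({gene!r}, {phenotype!r}) to remove")
        B[i, j] = 0.0
        return AssociationTable(self.gene_ids, self.phenotype_ids, B)

    def bridging_genes(self) -> Set[str]:
        return {
            g for g, s in zip(self.gene_ids, self.incidence.sum(axis=1)) if s > 0
        }

    def bridging_phenotypes(self) -> Set[str]:
        return {
            p for p, s in zip(self.phenotype_ids, self.incidence.sum(axis=0)) if s > 0
        }


@dataclass(frozen=True)
class HeterogeneousNetwork:
    """Gene multigraph + phenotype network + associations, with walk parameters."""

    genes: GeneMultigraph
    phenotypes: WeightedNetwork
    associations: AssociationTable
    lam: float = 0.5
    eta: float = 0.5

    def __post_init__(self):
        # lam = 0 is admitted as the exact decoupled limit (block-diagonal
        # matrix, no cross-subnetwork jumps); lam = 1 would strand bridging rows.
        if not (0 <= self.lam < 1):
            raise ValidationError(f"lambda must be in [0, 1), got {self.lam}")
        if not (0 < self.eta < 1):
            raise ValidationError(f"eta must be in (0, 1), got {self.eta}")
        missing_g = set(self.associations.gene_ids) - set(self.genes.universe)
        if missing_g:
            raise ValidationError(
                f"association genes not in gene universe: {sorted(missing_g)}"
            )
        missing_p = set(self.associations.phenotype_ids) - set(
            self.phenotypes.node_ids
        )
        if missing_p:
            raise ValidationError(
                f"association phenotypes not in phenotype network: {sorted(missing_p)}"
            )
        clash = set(self.genes.universe) & set(self.phenotypes.node_ids)
        if clash:
            raise ValidationError(
                f"gene and phenotype identifiers collide: {sorted(clash)}"
            )

    @property
    def node_ids(self) -> Tuple[str, ...]:
        return self.genes.universe + self.phenotypes.node_ids


def _aligned_incidence(h: HeterogeneousNetwork) -> np.ndarray:
    """B re-indexed to (gene universe order) x (phenotype network order)."""
    assoc = h.associations
    Ng, Np = len(h.genes.universe), len(h.phenotypes.node_ids)
    B = np.zeros((Ng, Np))
    gpos = {g: i for i, g in enumerate(h.genes.universe)}
    ppos = {p: i for i, p in enumerate(h.phenotypes.node_ids)}
    for gi, g in enumerate(assoc.gene_ids):
        for pj, p in enumerate(assoc.phenotype_ids):
            if assoc.incidence[gi, pj]:
                B[gpos[g], ppos[p]] = 1.0
    return B


def assemble_block(
    M_G: np.ndarray,
    M_P: np.ndarray,
    B: np.ndarray,
    lam: float,
    node_ids: Tuple[str, ...],
) -> TransitionMatrix:
    """Assemble the CHN block matrix from precomputed intra-subnetwork matrices.

    Rows of bridging nodes split (1 - lam) intra / lam inter. A bridging node
    whose intra row is empty (no edges in its home subnetwork) would leak the
    (1 - lam) mass, so its full mass is renormalised onto the inter block;
    symmetrically a node with intra edges but no associations keeps mass 1 at
    home. Every row of the result sums to one.
    """
    Ng, Np = M_G.shape[0], M_P.shape[0]
    g_assoc = B.sum(axis=1)
    p_assoc = B.sum(axis=0)
    g_intra = M_G.sum(axis=1)
    p_intra = M_P.sum(axis=1)

    def row_scales(intra: np.ndarray, assoc: np.ndarray, side: str):
        intra_scale = np.where(assoc > 0, 1.0 - lam, 1.0)
        inter_scale = np.where(assoc > 0, lam, 0.0)
        degenerate = (assoc > 0) & (intra <= 0)
        if degenerate.any():
            logger.warning(
                "%d bridging %s node(s) have no intra-subnetwork edges; "
                "their full transition mass goes to the other subnetwork",
                int(degenerate.sum()),
                side,
            )
            intra_scale = np.where(degenerate, 0.0, intra_scale)
            inter_scale = np.where(degenerate, 1.0, inter_scale)
        return intra_scale, inter_scale

    g_intra_s, g_inter_s = row_scales(g_intra, g_assoc, "gene")
    p_intra_s, p_inter_s = row_scales(p_intra, p_assoc, "phenotype")

    GP = np.zeros((Ng, Np))
    rows = g_assoc > 0
    GP[rows] = B[rows] / g_assoc[rows, None]
    PG = np.zeros((Np, Ng))
    cols = p_assoc > 0
    PG[cols] = B.T[cols] / p_assoc[cols, None]

    top = np.hstack([g_intra_s[:, None] * M_G, g_inter_s[:, None] * GP])
    bottom = np.hstack([p_inter_s[:, None] * PG, p_intra_s[:, None] * M_P])
    return TransitionMatrix(node_ids=node_ids, probs=np.vstack([top, bottom]))


def chn_transition(h: HeterogeneousNetwork) -> TransitionMatrix:
    """Block transition matrix of the heterogeneous network (genes then phenotypes)."""
    M_G = merge_transition(h.genes).probs
    M_P = transition_from_network(h.phenotypes).probs
    B = _aligned_incidence(h)
    return assemble_block(M_G, M_P, B, h.lam, h.node_ids)


def chn_initial(
    node_ids: Sequence[str],
    n_genes: int,
    gene_seeds: Set[str],
    phenotype_seeds: Set[str],
    eta: float,
) -> InitialDistribution:
    """Restart vector [(1 - eta) * u0 ; eta * v0] over genes then phenotypes.

    If one side has no seeds the full unit mass goes to the other side
    (logged), keeping the total at one.
    """
    if not gene_seeds and not phenotype_seeds:
        raise ValidationError("no seed nodes on either side")
    ids = tuple(node_ids)
    gene_part, phen_part = set(ids[:n_genes]), set(ids[n_genes:])
    bad_g = gene_seeds - gene_part
    if bad_g:
        raise ValidationError(f"gene seeds not in gene universe: {sorted(bad_g)}")
    bad_p = phenotype_seeds - phen_part
    if bad_p:
        raise ValidationError(
            f"phenotype seeds not in phenotype network: {sorted(bad_p)}"
        )
    if not gene_seeds:
        logger.info("no gene seeds: full restart mass on the phenotype side")
        g_mass, p_mass = 0.0, 1.0
    elif not phenotype_seeds:
        logger.info("no phenotype seeds: full restart mass on the gene side")
        g_mass, p_mass = 1.0, 0.0
    else:
        g_mass, p_mass = 1.0 - eta, eta
    p0 = np.zeros(len(ids))
    pos = {x: i for i, x in enumerate(ids)}
    for s in gene_seeds:
        p0[pos[s]] = g_mass / len(gene_seeds)
    for s in phenotype_seeds:
        p0[pos[s]] = p_mass / len(phenotype_seeds)
    return InitialDistribution(node_ids=ids, p0=p0)


@dataclass(frozen=True)
class ChnStationary:
    """Stationary distribution split into gene and phenotype components."""

    gene_ids: Tuple[str, ...]
    phenotype_ids: Tuple[str, ...]
    u: np.ndarray
    v: np.ndarray
    iterations: int
    residual: float

    def gene_score(self, gene: str) -> float:
        return float(self.u[self.gene_ids.index(gene)])


def chn_walk(
    h: HeterogeneousNetwork,
    gene_seeds: Set[str],
    phenotype_seeds: Set[str],
    cfg: WalkConfig = WalkConfig(),
    M: TransitionMatrix | None = None,
) -> ChnStationary:
    """Run the restart walk on the block matrix and split the stationary vector."""
    if M is None:
        M = chn_transition(h)
    n_genes = len(h.genes.universe)
    p0 = chn_initial(M.node_ids, n_genes, gene_seeds, phenotype_seeds, h.eta)
    res = rwr(M, p0, cfg)
    return ChnStationary(
        gene_ids=h.genes.universe,
        phenotype_ids=h.phenotypes.node_ids,
        u=res.p[:n_genes],
        v=res.p[n_genes:],
        iterations=res.iterations,
        residual=res.residual,
    )


def chn_rank(
    h: HeterogeneousNetwork,
    gene_seeds: Set[str],
    phenotype_seeds: Set[str],
    candidates: Set[str],
    cfg: WalkConfig = WalkConfig(),
    M: TransitionMatrix | None = None,
) -> Tuple[List[Tuple[str, float]], List[Tuple[str, float]]]:
    """Rank candidate genes by u-infinity and phenotypes by v-infinity.

    Ties are broken by ascending identifier; candidates must be genes.
    """
    bad = set(candidates) - set(h.genes.universe)
    if bad:
        raise ValidationError(f"candidates not in gene universe: {sorted(bad)}")
    stat = chn_walk(h, gene_seeds, phenotype_seeds, cfg, M=M)
    gscores = dict(zip(stat.gene_ids, stat.u))
    ranked_genes = sorted(
        ((c, float(gscores[c])) for c in set(candidates)),
        key=lambda cs: (-cs[1], cs[0]),
    )
    ranked_phens = sorted(
        zip(stat.phenotype_ids, map(float, stat.v)), key=lambda cs: (-cs[1], cs[0])
    )
    return ranked_genes, ranked_phens
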