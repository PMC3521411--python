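"""Leave-one-out benchmarking protocol for disease-gene prioritization.

For each disease gene, the gene is held out, the remaining genes of its
disease serve as seeds, and the method ranks a candidate set consisting of
the held-out gene plus its nearest chromosomal neighbours (an artificial
linkage interval, 100 candidates by default). The rank of the held-out gene
across all trials yields the ROC/AUC; for the heterogeneous-network variant
the figure of merit is the number of trials where the held-out gene ranks
strictly first ("successful predictions"). The protocol contains no
randomness: given fixed inputs the result is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chn import AssociationTable, HeterogeneousNetwork, assemble_block, chn_initial
from .exceptions import ValidationError
from .graph_core import SimilarityMatrix, build_knn_graph, transition_from_network
from .walk import (
    GeneMultigraph,
    InitialDistribution,
    WalkConfig,
    merge_transition,
    rank_candidates,
    rwr,
)

logger = logging.getLogger(__name__)

DEFAULT_INTERVAL_SIZE = 99


@dataclass(frozen=True)
class GenePosition:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError(
                f"gene position start {self.start} must be < end {self.end}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GenePositionTable:
    """One chromosomal location per gene (1-based inclusive coordinates)."""

    positions: Mapping[str, GenePosition]

    def __post_init__(self):
        object.__setattr__(self, "positions", dict(self.positions))

    def __contains__(self, gene: str) -> bool:
        return gene in self.positions

    def __getitem__(self, gene: str) -> GenePosition:
        return self.positions[gene]

    @property
    def genes(self) -> List[str]:
        return sorted(self.positions)


@dataclass(frozen=True)
class Trial:
    disease: str
    held_out: str
    candidate_count: int
    rank: int
    success: bool


@dataclass(frozen=True)
class LoocvResult:
    """Per-trial ranks plus aggregate AUC and strict rank-1 success count."""

    trials: Tuple[Trial, ...]

    def __post_init__(self):
        object.__setattr__(self, "trials", tuple(self.trials))
        for t in self.trials:
            if not (1 <= t.rank <= t.candidate_count):
                raise ValidationError(
                    f"trial rank {t.rank} outside 1..{t.candidate_count}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def success_count(self) -> int:
        return sum(1 for t in self.trials if t.success)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (t.disease, t.held_out, t.candidate_count, t.rank, t.success)
                for t in self.trials
            ],
            columns=["disease", "held_out_gene", "candidate_count", "rank", "success"],
        )


def linkage_interval(
    held_out: str, positions: GenePositionTable, n: int = DEFAULT_INTERVAL_SIZE
) -> Set[str]:
    """Held-out gene plus its ``n`` nearest same-chromosome genes by midpoint.

    Distance ties are broken by ascending identifier. If the chromosome has
    fewer than ``n`` other genes all of them are taken (with a warning), so
    the candidate set may be smaller than ``n + 1``.
    """
    if held_out not in positions:
        raise ValidationError(f"held-out gene {held_out!r} missing from position table")
    target = positions[held_out]
    others = [
        (abs(positions[g].midpoint - target.midpoint), g)
        for g in positions.genes
        if g != held_out and positions[g].chrom == target.chrom
    ]
    others.sort()
    if len(others) < n:
        logger.warning(
            "chromosome %s has only %d genes besides %s (requested %d)",
            target.chrom,
            len(others),
            held_out,
            n,
        )
    return {held_out} | {g for _, g in others[:n]}


@dataclass(frozen=True)
class DiseaseGeneSets:
    """Disease identifier -> set of known disease genes."""

    sets: Mapping[str, frozenset]

    def __post_init__(self):
        object.__setattr__(
            self, "sets", {d: frozenset(g) for d, g in self.sets.items()}
        )

    def restricted_to(self, universe: Set[str]) -> "DiseaseGeneSets":
        """Drop genes outside the network universe (logged)."""
        out = {}
        for d in sorted(self.sets):
            kept = self.sets[d] & universe
            dropped = self.sets[d] - universe
            if dropped:
                logger.warning(
                    "disease %s: %d gene(s) outside the network dropped: %s",
                    d,
                    len(dropped),
                    sorted(dropped),
                )
            out[d] = kept
        return DiseaseGeneSets(out)


def _held_out_rank(
    ranked: List[Tuple[str, float]], held_out: str
) -> Tuple[int, bool]:
    """Rank of the held-out gene (ties by ascending id) and strict-top success."""
    rank = next(i for i, (g, _) in enumerate(ranked, start=1) if g == held_out)
    score = dict(ranked)[held_out]
    success = all(score > s for g, s in ranked if g != held_out)
    return rank, success


def _candidate_set(
    held_out: str,
    seeds: Set[str],
    positions: GenePositionTable,
    universe: Set[str],
    n_interval: int,
) -> Set[str]:
    cands = linkage_interval(held_out, positions, n_interval)
    outside = cands - universe
    if outside:
        logger.warning(
            "%d candidate gene(s) outside the network dropped: %s",
            len(outside),
            sorted(outside),
        )
        cands -= outside
    overlap = cands & seeds
    if overlap:
        logger.warning(
            "%d candidate(s) are seeds and were removed: %s",
            len(overlap),
            sorted(overlap),
        )
        cands -= overlap
    return cands


def loocv_rwrm(
    sets: DiseaseGeneSets,
    mg: GeneMultigraph,
    positions: GenePositionTable,
    cfg: WalkConfig = WalkConfig(),
    n_interval: int = DEFAULT_INTERVAL_SIZE,
) -> LoocvResult:
    """Leave-one-out over every (disease, gene) pair on the merged multigraph.

    One trial per usable disease gene: hold it out, seed the rest of the
    disease's genes, rank the linkage-interval candidates. Diseases with
    fewer than two usable genes are skipped with a warning.
    """
    universe = set(mg.universe)
    usable = sets.restricted_to(universe)
    M = merge_transition(mg)
    trials: List[Trial] = []
    for disease in sorted(usable.sets):
        genes = usable.sets[disease]
        if len(genes) < 2:
            logger.warning(
                "disease %s has %d usable gene(s); needs >= 2, skipped",
                disease,
                len(genes),
            )
            continue
        for held_out in sorted(genes):
            seeds = set(genes) - {held_out}
            cands = _candidate_set(held_out, seeds, positions, universe, n_interval)
            p0 = InitialDistribution.uniform_over(M.node_ids, seeds)
            res = rwr(M, p0, cfg)
            ranked = rank_candidates(res, cands)
            rank, success = _held_out_rank(ranked, held_out)
            trials.append(Trial(disease, held_out, len(cands), rank, success))
    return LoocvResult(trials=tuple(trials))


def rank_auc(
    result: LoocvResult,
) -> Tuple[float, Dict[str, float], pd.DataFrame]:
    """Pooled and per-disease AUC from held-out ranks, plus ROC points.

    A trial of rank ``r`` among ``n`` candidates contributes ``(n - r) /
    (n - 1)``: the fraction of decoy candidates ranked below the true gene
    (the Mann-Whitney statistic for one positive vs n-1 negatives). The
    overall AUC pools all trials; per-disease AUC averages within disease.
    Trials with a single candidate carry no ranking information and are
    excluded with a warning. ROC points are (1 - specificity, sensitivity)
    over rank thresholds.
    """
    usable = [t for t in result.trials if t.candidate_count > 1]
    skipped = result.n_trials - len(usable)
    if skipped:
        logger.warning("%d single-candidate trial(s) excluded from AUC", skipped)
    if not usable:
        raise ValidationError("no trials with more than one candidate")
    contrib = np.array(
        [(t.candidate_count - t.rank) / (t.candidate_count - 1) for t in usable]
    )
    overall = float(contrib.mean())
    per_disease: Dict[str, float] = {}
    for d in sorted({t.disease for t in usable}):
        per_disease[d] = float(
            np.mean([c for c, t in zip(contrib, usable) if t.disease == d])
        )
    max_n = max(t.candidate_count for t in usable)
    rows = []
    for thr in range(0, max_n + 1):
        tpr = float(np.mean([t.rank <= thr for t in usable]))
        fpr = float(
            np.mean(
                [
                    (min(thr, t.candidate_count) - (t.rank <= thr))
                    / (t.candidate_count - 1)
                    for t in usable
                ]
            )
        )
        rows.append((fpr, tpr))
    roc = pd.DataFrame(rows, columns=["fpr", "tpr"])
    return overall, per_disease, roc


def loocv_chn(
    pgrs: AssociationTable,
    h: HeterogeneousNetwork,
    positions: GenePositionTable,
    cfg: WalkConfig = WalkConfig(),
    n_interval: int = DEFAULT_INTERVAL_SIZE,
) -> LoocvResult:
    """Leave-one-out over gene-phenotype associations on the heterogeneous network.

    Per association: remove it, seed the target phenotype plus its remaining
    genes, rank the held-out gene's linkage interval, and record a success
    when the held-out gene scores strictly higher than every other candidate.
    Associations whose gene is outside the gene universe are skipped (logged).
    """
    universe = set(h.genes.universe)
    M_G = merge_transition(h.genes).probs
    M_P = transition_from_network(h.phenotypes).probs
    node_ids = h.node_ids
    n_genes = len(h.genes.universe)
    gpos = {g: i for i, g in enumerate(h.genes.universe)}
    ppos = {p: i for i, p in enumerate(h.phenotypes.node_ids)}
    B_full = np.zeros((n_genes, len(h.phenotypes.node_ids)))
    for gene, phenotype in pgrs.pairs():
        if gene in gpos and phenotype in ppos:
            B_full[gpos[gene], ppos[phenotype]] = 1.0
    trials: List[Trial] = []
    for gene, phenotype in pgrs.pairs():
        if gene not in universe:
            logger.warning("held-out gene %s outside the network; trial skipped", gene)
            continue
        if phenotype not in ppos:
            logger.warning(
                "target phenotype %s outside the phenotype network; trial skipped",
                phenotype,
            )
            continue
        i, j = gpos[gene], ppos[phenotype]
        B_full[i, j] = 0.0
        gene_seeds = {
            h.genes.universe[gi] for gi in np.nonzero(B_full[:, j])[0]
        }
        cands = _candidate_set(gene, gene_seeds, positions, universe, n_interval)
        M = assemble_block(M_G, M_P, B_full, h.lam, node_ids)
        p0 = chn_initial(node_ids, n_genes, gene_seeds, {phenotype}, h.eta)
        res = rwr(M, p0, cfg)
        scores = {c: float(res.p[gpos[c]]) for c in cands}
        ranked = sorted(scores.items(), key=lambda cs: (-cs[1], cs[0]))
        rank, success = _held_out_rank(ranked, gene)
        trials.append(Trial(phenotype, gene, len(cands), rank, success))
        B_full[i, j] = 1.0
    return LoocvResult(trials=tuple(trials))


def k_sweep(
    k_values: Sequence[int],
    phenotype_similarity: SimilarityMatrix,
    mg: GeneMultigraph,
    pgrs: AssociationTable,
    positions: GenePositionTable,
    cfg: WalkConfig = WalkConfig(),
    lam: float = 0.5,
    eta: float = 0.5,
    n_interval: int = DEFAULT_INTERVAL_SIZE,
) -> pd.DataFrame:
    """Rebuild the phenotype KNN graph for each K and rerun the CHN LOOCV.

    Returns a table with one row per K: trial count and strict rank-1
    success count. Errors from KNN construction (e.g. K >= phenotype count)
    propagate to the caller.
    """
    if not k_values:
        raise ValidationError("k_values is empty")
    rows = []
    for k in k_values:
        phen_net = build_knn_graph(phenotype_similarity, k)
        kept = [
            (g, p)
            for g, p in pgrs.pairs()
            if g in set(mg.universe) and p in set(phen_net.node_ids)
        ]
        if len(kept) < len(pgrs.pairs()):
            logger.warning(
                "k=%d: %d association(s) fall outside the networks and are dropped",
                k,
                len(pgrs.pairs()) - len(kept),
            )
        usable_pgrs = AssociationTable.from_pairs(kept)
        h = HeterogeneousNetwork(mg, phen_net, usable_pgrs, lam, eta)
        res = loocv_chn(usable_pgrs, h, positions, cfg, n_interval)
        rows.append((k, res.n_trials, res.success_count))
    return pd.DataFrame(rows, columns=["k", "n_trials", "success_count"])
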