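"""TSV readers and writers for every table dialect the package consumes.

All tables are tab-separated; identifiers are whitespace-trimmed and
case-preserved. Readers reject malformed input with ``file:line`` context
rather than repairing it; writers emit deterministic row and column order so
identical inputs produce byte-identical files.

Dialects:
  edge list            node_a <TAB> node_b <TAB> weight   (weight optional, 1.0)
  similarity matrix    first row / first column are node identifiers
  associations         gene <TAB> phenotype
  positions            gene <TAB> chrom <TAB> start <TAB> end  (1-based inclusive)
  disease sets         disease <TAB> gene
  annotations          gene <TAB> term
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chn import AssociationTable
from .evaluation import DiseaseGeneSets, GenePosition, GenePositionTable, LoocvResult
from .exceptions import ValidationError
from .graph_core import AnnotationTable, SimilarityMatrix, WeightedNetwork

logger = logging.getLogger(__name__)


def _rows(path) -> Iterable[Tuple[int, List[str]]]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, [f.strip() for f in line.split("\t")]


def read_edge_list(path) -> WeightedNetwork:
    """Undirected weighted edge list; duplicate pairs rejected with line numbers."""
    edges: List[Tuple[str, str, float]] = []
    first_seen: Dict[Tuple[str, str], int] = {}
    for lineno, fields in _rows(path):
        if len(fields) not in (2, 3):
            raise ValidationError(f"{path}:{lineno}: expected 2 or 3 columns")
        a, b = fields[0], fields[1]
        if not a or not b:
            raise ValidationError(f"{path}:{lineno}: empty node identifier")
        if a == b:
            raise ValidationError(f"{path}:{lineno}: self-loop on {a!r}")
        try:
            w = float(fields[2]) if len(fields) == 3 else 1.0
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: weight {fields[2]!r} is not a number")
        if not w > 0:
            raise ValidationError(f"{path}:{lineno}: weight must be > 0, got {w}")
        key = tuple(sorted((a, b)))
        if key in first_seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate edge ({a!r}, {b!r}), "
                f"first seen at line {first_seen[key]}"
            )
        first_seen[key] = lineno
        edges.append((a, b, w))
    if not edges:
        raise ValidationError(f"{path}: no edges found")
    return WeightedNetwork.from_edges(edges)


def write_edge_list(net: WeightedNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w:.6f}\n")


def read_similarity(path) -> SimilarityMatrix:
    """Square similarity matrix with identifiers in the first row and column."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except FileNotFoundError:
        raise ValidationError(f"file not found: {path}")
    except Exception as exc:  # malformed table
        raise ValidationError(f"{path}: cannot parse similarity matrix: {exc}")
    rows = [str(x).strip() for x in df.index]
    cols = [str(x).strip() for x in df.columns]
    if rows != cols:
        raise ValidationError(f"{path}: row and column identifiers differ")
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-6, rtol=0):
        worst = float(np.abs(values - values.T).max())
        raise ValidationError(f"{path}: matrix asymmetric beyond 1e-6 (max {worst:.3g})")
    return SimilarityMatrix(node_ids=tuple(rows), values=(values + values.T) / 2)


def write_similarity(sim: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.values, index=sim.node_ids, columns=sim.node_ids)
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_associations(path) -> AssociationTable:
    """Two-column gene-phenotype association table; duplicates rejected."""
    pairs: List[Tuple[str, str]] = []
    first_seen: Dict[Tuple[str, str], int] = {}
    for lineno, fields in _rows(path):
        if len(fields) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns")
        g, p = fields
        if not g or not p:
            raise ValidationError(f"{path}:{lineno}: empty identifier")
        if (g, p) in first_seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate pair ({g!r}, {p!r}), "
                f"first seen at line {first_seen[(g, p)]}"
            )
        first_seen[(g, p)] = lineno
        pairs.append((g, p))
    return AssociationTable.from_pairs(pairs)


def write_associations(assoc: AssociationTable, path) -> None:
    with open(path, "w") as fh:
        for g, p in assoc.pairs():
            fh.write(f"{g}\t{p}\n")


def read_positions(path, zero_based: bool = False) -> GenePositionTable:
    """Gene positions `gene chrom start end`; BED-style input with zero_based=True."""
    positions: Dict[str, GenePosition] = {}
    for lineno, fields in _rows(path):
        if len(fields) != 4:
            raise ValidationError(f"{path}:{lineno}: expected 4 columns")
        gene, chrom, start_s, end_s = fields
        if gene in positions:
            raise ValidationError(f"{path}:{lineno}: duplicate gene {gene!r}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: non-integer coordinates")
        if zero_based:
            start += 1  # half-open zero-based -> 1-based inclusive
        if not start < end:
            raise ValidationError(f"{path}:{lineno}: start must be < end")
        positions[gene] = GenePosition(chrom=chrom, start=start, end=end)
    if not positions:
        raise ValidationError(f"{path}: no positions found")
    return GenePositionTable(positions=positions)


def write_positions(table: GenePositionTable, path) -> None:
    with open(path, "w") as fh:
        for gene in table.genes:
            p = table[gene]
            fh.write(f"{gene}\t{p.chrom}\t{p.start}\t{p.end}\n")


def read_disease_sets(path) -> DiseaseGeneSets:
    """Two-column `disease gene` table; duplicate pairs rejected."""
    sets: Dict[str, Set[str]] = {}
    first_seen: Dict[Tuple[str, str], int] = {}
    for lineno, fields in _rows(path):
        if len(fields) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns")
        disease, gene = fields
        if (disease, gene) in first_seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate pair ({disease!r}, {gene!r}), "
                f"first seen at line {first_seen[(disease, gene)]}"
            )
        first_seen[(disease, gene)] = lineno
        sets.setdefault(disease, set()).add(gene)
    if not sets:
        raise ValidationError(f"{path}: no disease sets found")
    return DiseaseGeneSets(sets={d: frozenset(g) for d, g in sets.items()})


def write_disease_sets(sets: DiseaseGeneSets, path) -> None:
    with open(path, "w") as fh:
        for disease in sorted(sets.sets):
            for gene in sorted(sets.sets[disease]):
                fh.write(f"{disease}\t{gene}\n")


def read_annotations(path) -> AnnotationTable:
    """Two-column `gene term` table; a gene may appear on many lines."""
    terms: Dict[str, Set[str]] = {}
    for lineno, fields in _rows(path):
        if len(fields) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns")
        gene, term = fields
        terms.setdefault(gene, set()).add(term)
    if not terms:
        raise ValidationError(f"{path}: no annotations found")
    return AnnotationTable(terms={g: frozenset(t) for g, t in terms.items()})


def read_id_list(path) -> List[str]:
    """One identifier per line (seeds, candidates)."""
    ids: List[str] = []
    for lineno, fields in _rows(path):
        if len(fields) != 1:
            raise ValidationError(f"{path}:{lineno}: expected a single identifier")
        ids.append(fields[0])
    if not ids:
        raise ValidationError(f"{path}: empty identifier list")
    return ids


def write_rankings(ranked: Sequence[Tuple[str, float]], path) -> None:
    """Ranked list as `rank gene score` with scores at 6 decimal places."""
    with open(path, "w") as fh:
        fh.write("rank\tgene\tscore\n")
        for rank, (gene, score) in enumerate(ranked, start=1):
            fh.write(f"{rank}\t{gene}\t{score:.6f}\n")


def write_trials(result: LoocvResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def write_roc(roc: pd.DataFrame, path) -> None:
    roc.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_summary(summary: Mapping, path) -> None:
    """Summary JSON including configuration and library versions."""
    import networkx

    payload = dict(summary)
    payload["versions"] = {
        "multiwalk": _package_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("multiwalk")
    except PackageNotFoundError:
        return "unknown"
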