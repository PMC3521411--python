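# Methods

## Problem setting

Linkage analysis narrows a disease locus to dozens or hundreds of candidate
genes; network propagation ranks those candidates by their proximity to genes
already known to cause the disease. Because any single genomic data source
(protein–protein interactions, functional similarity derived from each of the
three ontology namespaces, …) is noisy and incomplete, this package merges
several gene networks into one *multigraph* — a graph that keeps one parallel
edge per data source between the same gene pair — and walks it directly,
instead of ranking per source and aggregating the rank lists afterwards.

## Random walk with restart (RWR)

For one weighted undirected network with symmetric adjacency `A`, the
transition matrix is the degree normalisation

    M[i, j] = A[i, j] / d(i),      d(i) = Σ_j A[i, j],

so a walker at `i` picks an incident edge with probability proportional to
its weight. The walk with restart iterates

    p_{s+1} = (1 − γ) Mᵀ p_s + γ p0,

where `p0` puts equal mass on each seed gene and γ is the restart
probability. The iteration map is affine with Lipschitz constant (1 − γ) in
L1, so it contracts geometrically to the unique fixed point
`p∞ = γ (I − (1 − γ) Mᵀ)⁻¹ p0`; the implementation iterates rather than
solving, and records the L1 residual and the total mass after every step.
Candidates are ranked by descending `p∞`, ties broken by ascending
identifier so output is reproducible.

## The multigraph merge (RWRM)

Let `N_i` be the number of layers in which gene `i` has at least one edge.
The walker at `i` first selects one of those layers (uniformly by default,
`q = 1/N_i`) and then steps inside it, so the merged transition probability
is the expectation over layers:

    M[i, j] = Σ_k q^(k) M^(k)[i, j]   (sum over layers containing i).

Each member layer contributes a full row of mass 1 weighted by `1/N_i`, so
merged rows sum to one exactly. "Contains i" is read as *has an edge at i*:
an edgeless presence would contribute an all-zero row and break
stochasticity, which is also why genes absent from every layer are rejected
at construction rather than silently carried. Per-layer weights other than
uniform are supported (they must sum to one over the layers containing each
node) but uniform is the default and the only setting exercised by the
benchmarks.

## Heterogeneous gene–phenotype network (CHN)

A phenotype similarity matrix (e.g. text-mining correlation of clinical
descriptions) is turned into a KNN graph: each phenotype is connected to its
K most similar partners, edges weighted by the similarity score, the edge set
being the union over nodes (so degrees may exceed K). The phenotype network
and the gene multigraph are joined by the binary association matrix `B`
(gene × phenotype). Nodes with at least one association are *bridging*; a
walker there jumps across with probability λ, spread uniformly over its
associations, and stays home with probability 1 − λ:

    M = [ M_G   M_GP ]      M_GP[i, ·] = λ B[i, ·] / Σ_j B[i, j]
        [ M_PG  M_P  ],     M_PG[i, ·] = λ B[·, i]ᵀ / Σ_g B[g, i],

with the bridging rows of `M_G` and `M_P` scaled by 1 − λ and internal rows
untouched. Transitions *from* phenotype `i` distribute λ over the genes
associated with phenotype `i` — i.e. column `i` of `B` — which is the only
reading under which the displayed 9×9 example rows (0.5 for a
one-association phenotype; 0.25/0.25 for a two-association phenotype) come
out. The restart vector is `p0 = [(1 − η) u0 ; η v0]` with `u0`, `v0`
uniform over the gene and phenotype seeds; if one side has no seeds the full
unit mass goes to the other side (logged), since anything else would leave
total mass below one.

Degenerate rows: a bridging node with associations but no edges in its home
subnetwork cannot split (1 − λ)/λ without leaking the home share, so its
entire row mass is renormalised onto the inter-subnetwork block, with a
warning. λ = 0 is admitted as the exact decoupled limit (block-diagonal
matrix); λ = 1 is rejected because it would strand every bridging row.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| γ | restart probability per step | 0.7 | the walk is insensitive over ≈0.6–0.9 |
| λ | cross-subnetwork jumping probability | 0.5 | 0 decouples the subnetworks |
| η | restart-mass share of the phenotype side | 0.5 | 0.5 weights both sides equally |
| K | phenotype / gene-functional KNN size | 5 | sweep available via `k_sweep` |
| tol | L1 convergence tolerance | 1e-10 | residual contracts by (1 − γ) per step |
| max_iter | iteration cap | 10 000 | exceeded ⇒ `ConvergenceError` (CLI exit 3) |

Gene functional similarity from annotation terms is the raw overlap count by
default, with a Jaccard-normalised variant exposed (`mode="jaccard"`); the
choice matters only through the KNN selection, which is scale-invariant per
column except for ties.

## Evaluation protocol

Leave-one-out cross validation over disease genes: hold one gene out, seed
the remaining genes of its disease (for the heterogeneous variant, the
target phenotype plus the phenotype's remaining genes), and rank a candidate
set of the held-out gene plus its 99 nearest same-chromosome genes.
"Nearest" is measured between interval midpoints (strand-agnostic, ties by
identifier); positions are 1-based inclusive, with a `zero_based` switch for
BED-style input. Seeds that fall inside the candidate interval are removed
from the candidate set (seeds and candidates must be disjoint for the rank
to be meaningful), and candidate genes absent from the network are dropped,
both with warnings.

A trial of rank `r` among `n` candidates contributes `(n − r)/(n − 1)` to
the AUC — the fraction of decoys ranked below the true gene, i.e. the
Mann–Whitney statistic for one positive versus `n − 1` negatives. The
overall AUC pools all trials; per-disease AUCs average within disease (both
are reported, since pooling and macro-averaging answer slightly different
questions). A *successful prediction* requires the held-out gene's score to
be **strictly** greater than every other candidate's — pessimistic on ties,
so tie artifacts can never inflate the success count. Trials with a single
candidate are successes by definition but are excluded from AUC. The whole
protocol is deterministic: rerunning it on the same inputs reproduces every
rank.

## Synthetic benchmark generator

`generate_benchmark` emulates the one structural assumption the method
exploits — similar phenotypes are caused by mutations in functionally
related genes — as planted modules: gene modules shared across layers
(within-module edge probability 0.9 vs background 0.01 by default, three
layers, module size 10), a block-structured phenotype similarity aligned to
the modules (0.8 within vs 0.1 background plus symmetric uniform noise in
[0, 0.05]), three gene–phenotype associations per module phenotype, one
disease per module, and gene positions assigned by a random permutation
along two synthetic chromosomes so that linkage intervals mix module and
background genes. Each artifact draws from its own RNG stream spawned from
`rng_seed`, so outputs are byte-identical across runs and adding a layer
never perturbs the other draws. Genes left isolated in every layer (rare
outside the null regime) receive one deterministic rescue edge in layer 1,
preserving the multigraph invariant.

Setting the background probabilities equal to the within-module ones removes
the signal entirely; the null benchmark used in the tests (20 modules of 10
genes in a 260-gene universe, edge probability 0.05 everywhere, 200 trials)
calibrates the AUC near 0.5. What the generator does **not** emulate: the
heavy-tailed degree distributions of real interactome data, ontology DAG
structure, ascertainment bias in curated associations, or realistic gene
density along chromosomes. Passing the recovery tests therefore shows the
algorithms are implemented correctly and are calibrated under no signal, not
that any particular accuracy will be achieved on real data.

## Numerical and design notes

- Problem sizes: toy examples are 5–9 nodes; synthetic benchmarks run at a
  few hundred genes, where dense `numpy` linear algebra is simplest and the
  full LOOCV completes in seconds. The merged matrix is computed once per
  benchmark and reused across trials; for the heterogeneous LOOCV the two
  intra-subnetwork blocks are precomputed and only the association-dependent
  scaling is reassembled per trial.
- KNN ties at the k-th similarity are broken by ascending identifier;
  similarities ≤ 0 never create edges (a zero-weight edge is
  indistinguishable from no edge under degree normalisation); self-similarity
  is excluded.
- Row sums of transition matrices are validated to 1e-9; similarity symmetry
  to 1e-6 at load time (then symmetrised by averaging).
- The 5×5 worked-example matrix is shipped as a display-rounded constant
  (`toy_merged_matrix_rounded`): its sparsity pattern cannot be reproduced
  from any undirected layer reconstruction, so the toy layer edge lists are
  built to satisfy the unambiguous inline values only, and one g3–g5 edge is
  included so every toy gene belongs to at least one layer. The example's
  displayed stationary value for g5 is not consistent with its own matrix
  under the update rule (exact computation gives ≈ 0.12); the g1–g4 entries
  reproduce at two decimals with γ = 0.7.
- All readers reject rather than repair malformed input, reporting
  `file:line`; all writers emit deterministic row/column order. When a YAML
  config is passed to the CLI its values override command-line flags for the
  keys it defines.

## Known limitations

- Dense matrices bound practical problem size to a few thousand nodes;
  genome-scale networks would need a sparse backend.
- Phenotype similarity is consumed, never computed: no text mining is
  included.
- Only two node types (genes, phenotypes) are supported; `B` is binary —
  weighted associations are accepted but normalised identically.
- Directed input graphs and teleportation variants (degree-biased restart,
  lazy walks) are out of scope.
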