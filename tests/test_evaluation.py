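"""Linkage intervals, LOOCV protocol, rank-based AUC, K-sweep."""

import numpy as np
import pytest
from scipy import stats

from multiwalk import (
    DiseaseGeneSets,
    GenePosition,
    GenePositionTable,
    LoocvResult,
    Trial,
    ValidationError,
    WalkConfig,
    build_knn_graph,
    generate_benchmark,
    k_sweep,
    linkage_interval,
    loocv_chn,
    loocv_rwrm,
    rank_auc,
    HeterogeneousNetwork,
    SyntheticSpec,
)


def positions_on_line(n, chrom="chr1", spacing=1000):
    return GenePositionTable(
        positions={
            f"g{i:04d}": GenePosition(chrom=chrom, start=i * spacing + 1,
                                      end=i * spacing + 500)
            for i in range(n)
        }
    )


class TestLinkageInterval:
    def test_nearest_by_midpoint_brute_force(self):
        pos = positions_on_line(200)
        got = linkage_interval("g0050", pos, n=4)
        assert got == {"g0050", "g0048", "g0049", "g0051", "g0052"}

    def test_small_chromosome_takes_all(self):
        pos = positions_on_line(100)
        got = linkage_interval("g0007", pos, n=99)
        assert got == set(pos.genes)

    def test_default_interval_yields_100_candidates(self):
        pos = positions_on_line(300)
        assert len(linkage_interval("g0150", pos)) == 100

    def test_other_chromosomes_excluded(self):
        positions = dict(positions_on_line(10).positions)
        positions["far"] = GenePosition(chrom="chr2", start=5001, end=5500)
        got = linkage_interval("g0005", GenePositionTable(positions=positions), n=9)
        assert "far" not in got

    def test_distance_tie_broken_by_identifier(self):
        pos = positions_on_line(5)
        # g0001 and g0003 are equidistant from g0002: identifier picks g0001
        got = linkage_interval("g0002", pos, n=1)
        assert got == {"g0002", "g0001"}

    def test_missing_gene_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            linkage_interval("nope", positions_on_line(5))


@pytest.fixture(scope="module")
def easy_benchmark():
    return generate_benchmark(SyntheticSpec())


class TestLoocvRwrm:
    def test_trial_count_is_sum_of_set_sizes(self, easy_benchmark):
        mg, _, _, _, pos = easy_benchmark
        rng = np.random.default_rng(1)
        sizes = (6, 7, 8)
        genes = list(mg.universe)
        sets = {}
        start = 0
        for d, size in enumerate(sizes):
            sets[f"d{d}"] = frozenset(genes[start : start + size])
            start += size
        res = loocv_rwrm(DiseaseGeneSets(sets=sets), mg, pos)
        assert res.n_trials == sum(sizes)

    def test_small_diseases_skipped(self, easy_benchmark):
        mg, _, _, _, pos = easy_benchmark
        sets = DiseaseGeneSets(
            sets={"singleton": frozenset({mg.universe[0]}),
                  "pair": frozenset(mg.universe[1:3])}
        )
        res = loocv_rwrm(sets, mg, pos)
        assert res.n_trials == 2
        assert {t.disease for t in res.trials} == {"pair"}

    def test_genes_outside_network_dropped(self, easy_benchmark):
        mg, _, _, _, pos = easy_benchmark
        sets = DiseaseGeneSets(
            sets={"d": frozenset(set(mg.universe[:5]) | {"ghost1", "ghost2"})}
        )
        res = loocv_rwrm(sets, mg, pos)
        assert res.n_trials == 5

    def test_easy_regime_recovers_planted_modules(self, easy_benchmark):
        mg, _, _, sets, pos = easy_benchmark
        res = loocv_rwrm(sets, mg, pos)
        assert res.n_trials == 40
        assert res.success_count / res.n_trials >= 0.9

    def test_deterministic(self, easy_benchmark):
        mg, _, _, sets, pos = easy_benchmark
        assert loocv_rwrm(sets, mg, pos) == loocv_rwrm(sets, mg, pos)


class TestRankAuc:
    def test_perfect_ranking_gives_auc_one(self):
        res = LoocvResult(
            trials=tuple(Trial("d", f"g{i}", 100, 1, True) for i in range(10))
        )
        overall, per_disease, _ = rank_auc(res)
        assert overall == 1.0 and per_disease == {"d": 1.0}

    def test_worst_ranking_gives_auc_zero(self):
        res = LoocvResult(
            trials=tuple(Trial("d", f"g{i}", 100, 100, False) for i in range(10))
        )
        overall, _, _ = rank_auc(res)
        assert overall == 0.0

    def test_uniform_ranks_give_auc_half(self):
        rng = np.random.default_rng(42)
        trials = tuple(
            Trial("d", f"g{i}", 100, int(rng.integers(1, 101)), False)
            for i in range(500)
        )
        overall, _, _ = rank_auc(LoocvResult(trials=trials))
        assert abs(overall - 0.5) < 0.03

    def test_matches_mann_whitney_oracle(self):
        # one positive at rank r among n candidates <=> U test of the positive's
        # score against the n-1 decoy scores
        rng = np.random.default_rng(7)
        trials = []
        expected = []
        for i in range(20):
            n = int(rng.integers(2, 15))
            r = int(rng.integers(1, n + 1))
            trials.append(Trial("d", f"g{i}", n, r, r == 1))
            scores = np.arange(n, dtype=float)  # distinct scores
            positive = scores[n - r]  # rank r from the top
            decoys = np.delete(scores, n - r)
            u = stats.mannwhitneyu([positive], decoys, alternative="two-sided")
            expected.append(u.statistic / (n - 1))
        overall, _, _ = rank_auc(LoocvResult(trials=tuple(trials)))
        assert overall == pytest.approx(np.mean(expected), abs=1e-12)

    def test_single_candidate_trials_excluded(self):
        trials = (
            Trial("d", "a", 1, 1, True),
            Trial("d", "b", 5, 5, False),
        )
        overall, _, _ = rank_auc(LoocvResult(trials=trials))
        assert overall == 0.0

    def test_roc_endpoints(self):
        trials = tuple(
            Trial("d", f"g{i}", 10, r, r == 1) for i, r in enumerate([1, 3, 5, 10])
        )
        _, _, roc = rank_auc(LoocvResult(trials=trials))
        assert roc.iloc[0].tolist() == [0.0, 0.0]
        assert roc.iloc[-1].tolist() == [1.0, 1.0]
        assert roc["tpr"].is_monotonic_increasing
        assert roc["fpr"].is_monotonic_increasing


@pytest.fixture(scope="module")
def chn_setup():
    spec = SyntheticSpec(n_genes=60, n_modules=3, module_size=8,
                         n_phenotypes=6, pgr_per_module=3, rng_seed=5)
    mg, phen_sim, pgrs, _, pos = generate_benchmark(spec)
    phen_net = build_knn_graph(phen_sim, 2)
    return mg, phen_sim, phen_net, pgrs, pos


class TestLoocvChn:
    def test_one_trial_per_association(self, chn_setup):
        mg, _, phen_net, pgrs, pos = chn_setup
        h = HeterogeneousNetwork(mg, phen_net, pgrs, 0.5, 0.5)
        res = loocv_chn(pgrs, h, pos)
        assert res.n_trials == len(pgrs.pairs())

    def test_success_requires_strictly_top_score(self, chn_setup):
        mg, _, phen_net, pgrs, pos = chn_setup
        h = HeterogeneousNetwork(mg, phen_net, pgrs, 0.5, 0.5)
        res = loocv_chn(pgrs, h, pos)
        # strict-top success can never exceed the number of rank-1 trials
        assert res.success_count <= sum(1 for t in res.trials if t.rank == 1)
        for t in res.trials:
            if t.success:
                assert t.rank == 1

    def test_lambda_changes_success_count_reproducibly(self, chn_setup):
        mg, _, phen_net, pgrs, pos = chn_setup
        counts = {}
        for lam in (0.0, 0.5):
            h = HeterogeneousNetwork(mg, phen_net, pgrs, lam, 0.5)
            first = loocv_chn(pgrs, h, pos)
            second = loocv_chn(pgrs, h, pos)
            assert first == second
            counts[lam] = first.success_count
        assert counts[0.0] != counts[0.5]

    def test_candidate_set_of_one_is_a_success(self, easy_benchmark):
        mg, phen_sim, pgrs, _, _ = easy_benchmark
        phen_net = build_knn_graph(phen_sim, 2)
        h = HeterogeneousNetwork(mg, phen_net, pgrs, 0.5, 0.5)
        gene, phen = pgrs.pairs()[0]
        # a one-gene chromosome forces a single-candidate trial for that gene
        lonely = GenePositionTable(
            positions={
                g: GenePosition(chrom="chrX" if g == gene else "chr1",
                                start=i * 1000 + 1, end=i * 1000 + 500)
                for i, g in enumerate(mg.universe)
            }
        )
        single = type(pgrs).from_pairs(
            [(gene, phen)], gene_ids=pgrs.gene_ids, phenotype_ids=pgrs.phenotype_ids
        )
        res = loocv_chn(single, h, lonely, n_interval=99)
        assert res.n_trials == 1
        assert res.trials[0].candidate_count == 1
        assert res.success_count == 1


class TestKSweep:
    def test_single_k_matches_direct_loocv(self):
        spec = SyntheticSpec(n_genes=50, n_modules=2, module_size=8,
                             n_phenotypes=4, pgr_per_module=2, rng_seed=9)
        mg, phen_sim, pgrs, _, pos = generate_benchmark(spec)
        table = k_sweep([2], phen_sim, mg, pgrs, pos)
        phen_net = build_knn_graph(phen_sim, 2)
        h = HeterogeneousNetwork(mg, phen_net, pgrs, 0.5, 0.5)
        direct = loocv_chn(pgrs, h, pos)
        assert table.loc[0, "k"] == 2
        assert table.loc[0, "n_trials"] == direct.n_trials
        assert table.loc[0, "success_count"] == direct.success_count

    def test_k_at_least_phenotype_count_propagates_error(self):
        spec = SyntheticSpec(n_genes=50, n_modules=2, module_size=8,
                             n_phenotypes=4, pgr_per_module=2, rng_seed=9)
        mg, phen_sim, pgrs, _, pos = generate_benchmark(spec)
        with pytest.raises(ValidationError):
            k_sweep([4], phen_sim, mg, pgrs, pos)

    def test_deterministic_over_multiple_k(self):
        spec = SyntheticSpec(n_genes=50, n_modules=2, module_size=8,
                             n_phenotypes=6, pgr_per_module=2, rng_seed=9)
        mg, phen_sim, pgrs, _, pos = generate_benchmark(spec)
        t1 = k_sweep([2, 3], phen_sim, mg, pgrs, pos)
        t2 = k_sweep([2, 3], phen_sim, mg, pgrs, pos)
        assert t1.equals(t2)
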