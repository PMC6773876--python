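import itertools
import math

import numpy as np
import pytest

from pinora.enrichment import (
    EnrichmentConfig,
    EnrichmentRecord,
    adjust_pvalues,
    aggregate_subnetworks,
    filter_subnetworks,
    hypergeometric_ora,
    run_active_enrichment,
)
from pinora.search import SearchConfig, Subnetwork


def hypergeom_tail_oracle(N, K, n, x):
    """Exact upper-tail sum from integer binomial coefficients."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(x, min(K, n) + 1)
        if n - i <= N - K
    ) / denom


def _sub(genes, score, n_sig):
    return Subnetwork(
        genes=frozenset(genes), raw_score=score, score=score, n_significant=n_sig
    )


class TestFilterSubnetworks:
    def test_score_quantile_cut(self):
        subs = [_sub({f"G{i}"}, float(i), 10) for i in range(1, 11)]
        kept = filter_subnetworks(subs, score_quantile=0.80, min_sig_genes=1)
        assert sorted(s.score for s in kept) == [9.0, 10.0]

    def test_min_sig_genes_dominates_score(self):
        subs = [_sub({"A"}, 100.0, 9), _sub({"B"}, 1.0, 10), _sub({"C"}, 0.5, 10)]
        kept = filter_subnetworks(subs, score_quantile=0.0, min_sig_genes=10)
        assert all(s.n_significant >= 10 for s in kept)
        assert not any(s.score == 100.0 for s in kept)

    def test_single_subnetwork_kept(self):
        [kept] = filter_subnetworks([_sub({"A"}, 1.0, 10)])
        assert kept.score == 1.0

    def test_empty_input(self):
        assert filter_subnetworks([]) == []


class TestHypergeometricOra:
    def test_zero_overlap_p_is_one(self):
        p, fold, overlap = hypergeometric_ora({"A"}, {"B"}, {"A", "B", "C"})
        assert p == 1.0
        assert overlap == frozenset()

    def test_saturated_query(self):
        pool = {"A", "B", "C"}
        p, fold, overlap = hypergeometric_ora(pool, pool, pool)
        assert p == pytest.approx(1.0)
        assert fold == pytest.approx(1.0)

    def test_known_tail_sum(self):
        pool = {f"G{i}" for i in range(20)}
        pathway = {f"G{i}" for i in range(5)}
        query = {f"G{i}" for i in range(3)} | {f"G{i}" for i in range(10, 13)}
        p, fold, overlap = hypergeometric_ora(query, pathway, pool)
        assert p == pytest.approx(hypergeom_tail_oracle(20, 5, 6, 3), abs=1e-12)
        assert overlap == frozenset({"G0", "G1", "G2"})
        assert fold == pytest.approx((3 / 6) / (5 / 20))

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_ora({"A"}, {"A"}, set())

    def test_p_nonincreasing_in_overlap(self):
        # larger observed overlap can only make the upper tail smaller
        pool = [f"G{i}" for i in range(30)]
        pathway = set(pool[:8])
        ps = []
        for x in range(0, 7):
            query = set(pool[:x]) | set(pool[20 : 20 + (6 - x)])
            p, _, _ = hypergeometric_ora(query, pathway, pool)
            ps.append(p)
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestAdjustPvalues:
    def test_bonferroni(self):
        assert adjust_pvalues([0.01, 0.02], "bonferroni") == [0.02, 0.04]

    def test_bonferroni_caps_at_one(self):
        assert adjust_pvalues([0.9, 0.5, 0.5, 0.5], "bonferroni")[0] == 1.0

    def test_bh_hand_example(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            ps = list(rng.uniform(size=int(rng.integers(1, 11))))
            m = len(ps)
            order = np.argsort(ps)
            adj = [None] * m
            running = 1.0
            for rank_idx in range(m - 1, -1, -1):
                i = order[rank_idx]
                running = min(running, ps[i] * m / (rank_idx + 1))
                adj[i] = running
            assert adjust_pvalues(ps, "bh") == pytest.approx(adj, abs=1e-12)

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1], "holm-sidak-whatever")


class TestAggregate:
    def _rec(self, pid, adj_p, fold=1.0):
        return EnrichmentRecord(pid, adj_p / 2, adj_p, fold, frozenset())

    def test_lowest_p_wins_across_subnetworks(self):
        out = aggregate_subnetworks(
            [[self._rec("P", 0.01)], [self._rec("P", 0.03)]], threshold=0.05
        )
        assert out["P"].adj_p == 0.01

    def test_all_above_threshold_empty(self):
        out = aggregate_subnetworks([[self._rec("P", 0.5)]], threshold=0.05)
        assert out == {}

    def test_boundary_exactly_at_threshold_kept(self):
        out = aggregate_subnetworks([[self._rec("P", 0.05)]], threshold=0.05)
        assert "P" in out

    def test_tie_broken_by_fold_enrichment(self):
        out = aggregate_subnetworks(
            [[self._rec("P", 0.01, fold=2.0)], [self._rec("P", 0.01, fold=5.0)]],
        )
        assert out["P"].fold_enrichment == 5.0


class TestRunActiveEnrichment:
    def test_single_iteration_extremes_coincide(self, processed, pin, gene_sets):
        res = run_active_enrichment(
            processed,
            pin,
            gene_sets,
            SearchConfig(seed=0),
            EnrichmentConfig(iterations=1, seed=0),
        )
        assert len(res) > 0
        assert (res["lowest_p"] == res["highest_p"]).all()
        assert (res["occurrence"] == 1).all()

    def test_deterministic_greedy_occurrence_equals_iterations(
        self, processed, pin, gene_sets
    ):
        res = run_active_enrichment(
            processed,
            pin,
            gene_sets,
            SearchConfig(seed=0),
            EnrichmentConfig(iterations=3, seed=0),
        )
        assert (res["occurrence"] == 3).all()

    def test_planted_target_ranks_first(self, processed, pin, gene_sets):
        res = run_active_enrichment(
            processed,
            pin,
            gene_sets,
            SearchConfig(seed=0),
            EnrichmentConfig(iterations=1, seed=0),
        )
        assert res.iloc[0]["ID"] == "TARGET"
        assert (res["lowest_p"] <= res["highest_p"]).all()

    def test_up_down_split_by_change_sign(self, processed, pin, gene_sets):
        res = run_active_enrichment(
            processed,
            pin,
            gene_sets,
            SearchConfig(seed=0),
            EnrichmentConfig(iterations=1, seed=0),
        )
        row = res[res["ID"] == "TARGET"].iloc[0]
        up, down = set(row["Up_regulated"]), set(row["Down_regulated"])
        assert up  # planted module genes have positive changes
        assert up.isdisjoint(down)
        for gene in up:
            assert processed.change_values[gene] > 0
        for gene in down:
            assert processed.change_values[gene] < 0

    def test_empty_input_errors(self, pin, gene_sets):
        from pinora.input_processing import ProcessedInput

        empty = ProcessedInput(
            significant_genes=frozenset(), p_values={}, change_values={}
        )
        with pytest.raises(ValueError):
            run_active_enrichment(
                empty, pin, gene_sets, SearchConfig(), EnrichmentConfig()
            )


def test_removing_a_pathway_leaves_other_raw_ps_unchanged():
    pool = {f"G{i}" for i in range(30)}
    query = {f"G{i}" for i in range(8)}
    pathways = {
        "P1": {f"G{i}" for i in range(4)},
        "P2": {f"G{i}" for i in range(2, 10)},
        "P3": {f"G{i}" for i in range(20, 28)},
    }
    full = {pid: hypergeometric_ora(query, genes, pool)[0] for pid, genes in pathways.items()}
    without_p3 = {
        pid: hypergeometric_ora(query, genes, pool)[0]
        for pid, genes in pathways.items()
        if pid != "P3"
    }
    for pid in without_p3:
        assert without_p3[pid] == full[pid]
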