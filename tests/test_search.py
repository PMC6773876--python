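import math

import networkx as nx
import numpy as np
import pytest

from pinora.io_formats import InteractionNetwork
from pinora.scoring import CalibrationTable
from pinora.search import (
    SearchConfig,
    Subnetwork,
    connected_components,
    filter_overlapping,
    genetic_search,
    greedy_search,
    sa_acceptance,
    simulated_annealing_search,
)


def _pin(*edges):
    return InteractionNetwork.from_edges(edges)


def _sub(genes, score, n_sig=None):
    return Subnetwork(
        genes=frozenset(genes),
        raw_score=score,
        score=score,
        n_significant=n_sig if n_sig is not None else len(genes),
    )


def _assert_connected(pin, subnetworks):
    """Independent connectivity check through networkx traversal."""
    for sub in subnetworks:
        induced = pin.graph.subgraph(sub.genes)
        assert nx.is_connected(induced)


class TestConnectedComponents:
    def test_path_with_gap(self):
        pin = _pin(("A", "B"), ("B", "C"))
        assert connected_components(pin, {"A", "C"}) == [{"A"}, {"C"}]

    def test_triangle_all_on(self):
        pin = _pin(("A", "B"), ("B", "C"), ("C", "A"))
        assert connected_components(pin, {"A", "B", "C"}) == [{"A", "B", "C"}]

    def test_empty_input(self):
        assert connected_components(_pin(("A", "B")), set()) == []

    def test_gene_outside_pin_errors(self):
        with pytest.raises(ValueError):
            connected_components(_pin(("A", "B")), {"Z"})

    def test_matches_union_find_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            g = nx.gnp_random_graph(12, 0.2, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            pin = InteractionNetwork(g)
            on = {n for n in g.nodes if rng.random() < 0.5}

            # union-find oracle
            parent = {n: n for n in on}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b in g.edges:
                if a in on and b in on:
                    parent[find(a)] = find(b)
            oracle = {}
            for n in on:
                oracle.setdefault(find(n), set()).add(n)
            expected = sorted(
                (frozenset(c) for c in oracle.values()),
                key=lambda c: (-len(c), min(c)),
            )
            got = [frozenset(c) for c in connected_components(pin, on)]
            assert got == expected


class TestGreedy:
    def test_star_center_alone_when_leaves_dilute(self):
        pin = _pin(*[("HUB", f"L{i}") for i in range(6)])
        zmap = {"HUB": 3.0}
        calib = CalibrationTable(pin=pin, zmap=zmap, draws=500, seed=0)
        [sub] = greedy_search(pin, zmap, {"HUB"}, SearchConfig(), calib)
        assert sub.genes == {"HUB"}
        # premise: no single addition improves the calibrated score
        base = calib.score_genes({"HUB"})
        for leaf in pin.neighbors("HUB"):
            assert calib.score_genes({"HUB", leaf}) <= base

    def test_two_adjacent_significant_genes_join(self):
        chain = [(f"N{i}", f"N{i + 1}") for i in range(9)]
        pin = _pin(*chain)
        zmap = {"N4": 2.0, "N5": 2.0}
        calib = CalibrationTable(pin=pin, zmap=zmap, draws=500, seed=0)
        subs = greedy_search(pin, zmap, {"N4", "N5"}, SearchConfig(), calib)
        assert any(sub.genes == {"N4", "N5"} for sub in subs)
        # premise: the pair strictly outscores either singleton
        assert calib.score_genes({"N4", "N5"}) > calib.score_genes({"N4"})

    def test_depth_one_candidates_are_direct_neighbors_only(self):
        # three significant genes in a row; with max depth 1 the expansion
        # from the end seed cannot reach distance-2 genes
        pin = _pin(("A", "B"), ("B", "C"), ("C", "D"))
        zmap = {"A": 3.0, "B": 3.0, "C": 3.0}
        calib = CalibrationTable(pin=pin, zmap=zmap, draws=500, seed=0)
        subs = greedy_search(
            pin, zmap, {"A", "B", "C"}, SearchConfig(overlap_threshold=0.0), calib
        )
        for sub in subs:
            assert all(
                gene == sub.seed or gene in pin.neighbors(sub.seed)
                for gene in sub.genes
            )

    def test_no_seeds_errors(self, pin, zmap, calib):
        with pytest.raises(ValueError, match="no seeds"):
            greedy_search(pin, zmap, set(), SearchConfig(), calib)

    def test_planted_module_recovered(self, spec, pin, zmap, processed, calib):
        subs = greedy_search(
            pin, zmap, processed.significant_genes, SearchConfig(), calib
        )
        top = max(subs, key=lambda s: s.score)
        assert top.jaccard(set(spec.module_genes)) >= 0.6
        _assert_connected(pin, subs)


class TestFilterOverlapping:
    def test_duplicates_collapse(self):
        a, b = _sub("ABCD", 2.0), _sub("ABCD", 1.0)
        assert filter_overlapping([a, b]) == [a]

    def test_disjoint_all_kept(self):
        subs = [_sub("AB", 2.0), _sub("CD", 1.0), _sub("EF", 0.5)]
        assert filter_overlapping(subs) == subs

    def test_boundary_overlap_kept(self):
        a = _sub({"1", "2", "3", "4"}, 2.0)
        b = _sub({"3", "4", "5", "6"}, 1.0)  # overlap 2/4 = 0.5, not "more than"
        assert filter_overlapping([a, b], threshold=0.5) == [a, b]

    def test_kept_in_descending_score_order(self):
        subs = [_sub("AB", 1.0), _sub("CD", 3.0), _sub("EF", 2.0)]
        assert [s.score for s in filter_overlapping(subs)] == [3.0, 2.0, 1.0]


class TestSaAcceptance:
    def test_improvement_always_accepted(self):
        for t in (1e-6, 0.5, 10.0):
            assert sa_acceptance(1.1, 1.0, t) == 1.0

    def test_delta_minus_t_gives_inverse_e(self):
        assert sa_acceptance(0.0, 1.0, 1.0) == pytest.approx(math.exp(-1.0))

    def test_cold_limit_rejects(self):
        assert sa_acceptance(0.0, 1.0, 1e-6) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("t", [0.0, -1.0])
    def test_nonpositive_temperature_errors(self, t):
        with pytest.raises(ValueError):
            sa_acceptance(1.0, 0.0, t)


class TestSimulatedAnnealing:
    def _config(self, seed=0, iters=1500):
        return SearchConfig(algorithm="sa", seed=seed, sa_iterations=iters)

    def test_zero_iterations_returns_initial_components(self, pin, zmap, processed, calib):
        subs = simulated_annealing_search(
            pin, zmap, processed.significant_genes, self._config(iters=0), calib
        )
        assert subs
        _assert_connected(pin, subs)

    def test_deterministic_under_seed(self, pin, zmap, processed, calib):
        cfg = self._config(seed=7)
        first = simulated_annealing_search(
            pin, zmap, processed.significant_genes, cfg, calib
        )
        second = simulated_annealing_search(
            pin, zmap, processed.significant_genes, cfg, calib
        )
        assert first == second

    def test_beats_random_subsets_at_module_recovery(
        self, spec, pin, zmap, processed, calib
    ):
        module = set(spec.module_genes)
        rng = np.random.default_rng(123)
        nodes = sorted(pin.nodes)
        sa_jacs, random_jacs = [], []
        for seed in range(5):
            subs = simulated_annealing_search(
                pin, zmap, processed.significant_genes, self._config(seed=seed), calib
            )
            best = max(subs, key=lambda s: s.score)
            sa_jacs.append(best.jaccard(module))
            rand = set(rng.choice(nodes, size=len(best.genes), replace=False))
            random_jacs.append(
                len(rand & module) / len(rand | module)
            )
        assert np.mean(sa_jacs) > np.mean(random_jacs)


class TestGeneticAlgorithm:
    def _config(self, seed=0, pop=40, gens=25):
        return SearchConfig(
            algorithm="ga", seed=seed, ga_population=pop, ga_generations=gens
        )

    def test_elitism_gives_nondecreasing_best_fitness(self, pin, zmap, processed, calib):
        _, trace = genetic_search(
            pin,
            zmap,
            processed.significant_genes,
            self._config(),
            calib,
            return_trace=True,
        )
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_deterministic_under_seed(self, pin, zmap, processed, calib):
        cfg = self._config(seed=3)
        first = genetic_search(pin, zmap, processed.significant_genes, cfg, calib)
        second = genetic_search(pin, zmap, processed.significant_genes, cfg, calib)
        assert first == second

    def test_outputs_connected(self, pin, zmap, processed, calib):
        subs = genetic_search(
            pin, zmap, processed.significant_genes, self._config(), calib
        )
        assert subs
        _assert_connected(pin, subs)

    def test_tiny_population_errors(self, pin, zmap, processed, calib):
        with pytest.raises(ValueError):
            genetic_search(
                pin,
                zmap,
                processed.significant_genes,
                SearchConfig(algorithm="ga", ga_population=1),
                calib,
            )
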