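"""Centrality measures, essentiality calls and enrichment statistics."""

import itertools
import math

import numpy as np
import pytest

from influnet.coexpr import CoexpressionNetwork
from influnet.expression_io import EssentialityTable
from influnet.influence import InfluenceNetwork, build_influence_network
from influnet.netstats import (
    binomial_enrichment,
    call_hubs_bottlenecks,
    centrality_table,
    compare_proportions_fisher,
    enrichment_vs_background,
    essential_gene_set,
    out_degree,
    weighted_betweenness,
)


def brute_force_betweenness(inet: InfluenceNetwork, weight_mode: str) -> dict:
    """Exhaustive simple-path enumeration oracle for directed weighted
    betweenness with fractional attribution of tied shortest paths."""
    lengths = {
        e: (1.0 / w if weight_mode == "reciprocal" else w)
        for e, w in inet.directed_edges.items()
    }
    succ: dict = {n: [] for n in inet.nodes}
    for (a, b) in lengths:
        succ[a].append(b)
    score = {n: 0.0 for n in inet.nodes}
    for s in inet.nodes:
        for t in inet.nodes:
            if s == t:
                continue
            best, paths = math.inf, []
            stack = [([s], 0.0)]
            while stack:
                path, dist = stack.pop()
                node = path[-1]
                if dist > best + 1e-12:
                    continue
                if node == t:
                    if dist < best - 1e-12:
                        best, paths = dist, [path]
                    elif abs(dist - best) <= 1e-12:
                        paths.append(path)
                    continue
                for nxt in succ[node]:
                    if nxt not in path:
                        stack.append((path + [nxt], dist + lengths[(node, nxt)]))
            for path in paths:
                for inner in path[1:-1]:
                    score[inner] += 1.0 / len(paths)
    return score


def star_influence(n_leaves: int) -> InfluenceNetwork:
    edges = {tuple(sorted(("HUB", f"L{i}"))): 0.5 for i in range(n_leaves)}
    return build_influence_network(
        CoexpressionNetwork(nodes=["HUB"] + [f"L{i}" for i in range(n_leaves)], edges=edges)
    )


class TestOutDegree:
    def test_triangle_all_two(self, equal_triangle):
        inet = build_influence_network(equal_triangle)
        assert all(d == 2 for d in out_degree(inet).values())

    def test_star_and_isolated(self):
        net = CoexpressionNetwork(
            nodes=["HUB", "L0", "L1", "L2", "ZZ"],
            edges={("HUB", f"L{i}"): 0.4 for i in range(3)},
        )
        deg = out_degree(build_influence_network(net))
        assert deg["HUB"] == 3 and deg["L0"] == 1 and deg["ZZ"] == 0

    def test_equals_undirected_degree(self):
        from conftest import random_weighted_network

        net = random_weighted_network(np.random.default_rng(0), max_nodes=25)
        deg = out_degree(build_influence_network(net))
        undirected = {n: 0 for n in net.nodes}
        for a, b in net.edges:
            undirected[a] += 1
            undirected[b] += 1
        assert deg == undirected


class TestWeightedBetweenness:
    def test_path_graph_middle_node(self):
        net = CoexpressionNetwork(
            nodes=["A", "B", "C"], edges={("A", "B"): 0.6, ("B", "C"): 0.6}
        )
        btw = weighted_betweenness(build_influence_network(net))
        assert btw["B"] == pytest.approx(2.0)  # A->C and C->A
        assert btw["A"] == btw["C"] == 0.0

    def test_complete_equal_graph_all_zero(self):
        nodes = ["A", "B", "C", "D"]
        edges = {tuple(sorted(p)): 0.5 for p in itertools.combinations(nodes, 2)}
        btw = weighted_betweenness(
            build_influence_network(CoexpressionNetwork(nodes=nodes, edges=edges))
        )
        assert all(v == 0.0 for v in btw.values())

    @pytest.mark.parametrize("weight_mode", ["reciprocal", "as_distance"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, weight_mode, seed):
        from conftest import random_weighted_network

        rng = np.random.default_rng(seed)
        net = random_weighted_network(rng, max_nodes=7)
        inet = build_influence_network(net)
        got = weighted_betweenness(inet, weight_mode)
        expected = brute_force_betweenness(inet, weight_mode)
        for node in inet.nodes:
            assert got[node] == pytest.approx(expected[node], abs=1e-8)

    def test_unknown_mode_rejected(self, equal_triangle):
        with pytest.raises(ValueError, match="weight_mode"):
            weighted_betweenness(build_influence_network(equal_triangle), "bogus")


class TestHubsBottlenecks:
    def test_star_center_is_unique_hub(self):
        ct = centrality_table(star_influence(8))
        hubs, _ = call_hubs_bottlenecks(ct, "outlier")
        assert hubs == ["HUB"]

    def test_path_middle_is_top_bottleneck(self):
        nodes = list("ABCDE")
        edges = {("A", "B"): 0.5, ("B", "C"): 0.5, ("C", "D"): 0.5, ("D", "E"): 0.5}
        ct = centrality_table(
            build_influence_network(CoexpressionNetwork(nodes=nodes, edges=edges))
        )
        _, bottlenecks = call_hubs_bottlenecks(ct, "top_k", k=1)
        assert bottlenecks == ["C"]

    def test_all_equal_degrees_give_no_hubs(self, equal_triangle):
        ct = centrality_table(build_influence_network(equal_triangle))
        hubs, _ = call_hubs_bottlenecks(ct, "outlier")
        assert hubs == []


class TestEssentialGeneSet:
    def _table(self, pvals):
        pvals = np.asarray(pvals, dtype=float)
        return EssentialityTable(
            gene_ids=[f"G{i}" for i in range(pvals.shape[0])],
            cellline_ids=[f"CL{j}" for j in range(pvals.shape[1])],
            pvalues=pvals,
        )

    def test_threshold_is_inclusive(self):
        table = self._table([[0.05, 0.9], [0.051, 0.9]])
        assert essential_gene_set(table) == {"G0"}

    def test_all_above_threshold_excluded(self):
        assert essential_gene_set(self._table([[0.2, 0.6]])) == set()

    def test_all_missing_gene_excluded_with_warning(self):
        table = self._table([[np.nan, np.nan], [0.01, 0.5]])
        with pytest.warns(RuntimeWarning, match="no p-values"):
            assert essential_gene_set(table) == {"G1"}

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            essential_gene_set(self._table([[0.5]]), p_threshold=0.0)


class TestEnrichment:
    def test_binomial_all_successes_closed_form(self):
        assert binomial_enrichment(10, 10, 0.5).binomial_p == pytest.approx(0.5**10)

    def test_binomial_zero_successes_is_one(self):
        assert binomial_enrichment(0, 10, 0.3).binomial_p == 1.0

    def test_binomial_matches_exhaustive_sum(self):
        expected = sum(
            math.comb(10, i) * 0.3**i * 0.7 ** (10 - i) for i in range(7, 11)
        )
        assert binomial_enrichment(7, 10, 0.3).binomial_p == pytest.approx(expected, rel=1e-12)

    def test_binomial_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_enrichment(5, 3, 0.5)

    def test_fisher_diagonal_table(self):
        assert compare_proportions_fisher(2, 2, 0, 2).fisher_p == pytest.approx(1 / 3)

    def test_fisher_identical_proportions(self):
        assert compare_proportions_fisher(3, 6, 3, 6).fisher_p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_fisher_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(1, 15)), int(rng.integers(1, 15))
        k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
        got = compare_proportions_fisher(k1, n1, k2, n2).fisher_p
        total = k1 + k2
        support = range(max(0, total - n2), min(n1, total) + 1)
        probs = {
            x: math.comb(n1, x) * math.comb(n2, total - x) / math.comb(n1 + n2, total)
            for x in support
        }
        p_obs = probs[k1]
        expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
        assert got == pytest.approx(min(1.0, expected), rel=1e-8)

    def test_background_excludes_tested_set(self):
        result = enrichment_vs_background(
            selected={"A", "B"},
            network_genes={"A", "B", "C", "D", "E", "F"},
            essential={"A", "B", "C"},
        )
        assert result.essential_in_set == 2
        assert result.background_size == 4
        assert result.background_proportion == pytest.approx(0.25)

    def test_no_essential_genes_gives_p_one(self):
        result = enrichment_vs_background(
            selected={"A"}, network_genes={"A", "B", "C"}, essential=set()
        )
        assert result.binomial_p == 1.0
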