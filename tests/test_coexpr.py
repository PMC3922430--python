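"""Coexpression network construction and its permutation validation."""

import numpy as np
import pytest
from scipy import stats

from influnet.coexpr import (
    build_coexpression_network,
    partial_correlation_first_order,
    permutation_null,
    rank_transform,
)
from influnet.expression_io import ExpressionMatrix
from influnet.synthetic_data import GroundTruthSpec, simulate_ggm_expression


def one_group_matrix(values: np.ndarray) -> ExpressionMatrix:
    g, n = values.shape
    samples = [f"S{i}" for i in range(n)]
    return ExpressionMatrix(
        gene_ids=[f"G{i + 1}" for i in range(g)],
        sample_ids=samples,
        values=values,
        group_labels={s: "grp" for s in samples},
    )


class TestRankTransform:
    def test_distinct_values(self):
        m = one_group_matrix(np.array([[3.0, 1.0, 2.0]]))
        ranks, kept, dropped = rank_transform(m, "grp")
        np.testing.assert_array_equal(ranks[0], [3, 1, 2])
        assert kept == ["G1"] and dropped == []

    def test_average_rank_ties(self):
        m = one_group_matrix(np.array([[5.0, 5.0, 1.0]]))
        ranks, _, _ = rank_transform(m, "grp")
        np.testing.assert_array_equal(ranks[0], [2.5, 2.5, 1.0])

    def test_constant_gene_flagged_and_excluded(self):
        m = one_group_matrix(np.array([[1.0, 1.0, 1.0], [3.0, 1.0, 2.0]]))
        with pytest.warns(RuntimeWarning, match="constant"):
            _, kept, dropped = rank_transform(m, "grp")
        assert dropped == ["G1"] and kept == ["G2"]

    def test_spearman_invariant_under_monotone_map(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        m = one_group_matrix(np.vstack([x, np.exp(x)]))
        ranks, _, _ = rank_transform(m, "grp")
        assert np.corrcoef(ranks)[0, 1] == pytest.approx(1.0)


class TestPartialCorrelation:
    def test_conditioning_on_independent_gene_is_identity(self):
        assert partial_correlation_first_order(0.5, 0.0, 0.0) == 0.5

    def test_fully_explained_by_common_regulator(self):
        assert partial_correlation_first_order(0.9 * 0.8, 0.9, 0.8) == pytest.approx(0.0)

    def test_worked_example(self):
        value = partial_correlation_first_order(0.9, 0.9, 0.81)
        assert value == pytest.approx(0.171 / np.sqrt(0.19 * 0.3439), rel=1e-4)

    def test_degenerate_conditioner_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            partial_correlation_first_order(0.5, 1.0, 0.2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_residual_correlation_oracle(self, seed):
        """Formula equals the correlation of rank-regression residuals."""
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((3, 40)) + 0.5 * rng.standard_normal((1, 40))
        ranks = stats.rankdata(data, axis=1)
        r = np.corrcoef(ranks)
        got = partial_correlation_first_order(r[0, 1], r[0, 2], r[1, 2])

        def residual(y, z):
            beta = np.polyfit(z, y, 1)
            return y - np.polyval(beta, z)

        res_i = residual(ranks[0], ranks[2])
        res_j = residual(ranks[1], ranks[2])
        expected = np.corrcoef(res_i, res_j)[0, 1]
        assert got == pytest.approx(expected, abs=1e-8)


class TestBuildNetwork:
    def test_perfectly_correlated_pair_detected_with_weight_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        noise = rng.standard_normal((4, 100))
        m = one_group_matrix(np.vstack([x, np.exp(x), noise]))
        # the perfectly rank-correlated pair makes each member a
        # degenerate conditioner for the other's tests
        with pytest.warns(RuntimeWarning, match="skipped"):
            net = build_coexpression_network(m, "grp", alpha=0.01)
        assert ("G1", "G2") in net.edges
        assert net.edges[("G1", "G2")] > 0.95

    def test_common_regulator_edge_removed(self):
        """In a chain i-k-j the indirect i-j edge is screened out."""
        present = 0
        for seed in range(20):
            spec = GroundTruthSpec(
                n_genes=3, true_edges=frozenset({(0, 1), (1, 2)}),
                partial_correlation_strength=0.6, n_samples_per_group=500, seed=seed,
            )
            m, _ = simulate_ggm_expression(spec)
            net = build_coexpression_network(m, "untreated", alpha=0.01)
            assert ("G1", "G2") in net.edges and ("G2", "G3") in net.edges
            present += ("G1", "G3") in net.edges
        assert present <= 1

    def test_independent_genes_false_positive_rate_at_most_alpha(self):
        rates = []
        for seed in range(30):
            spec = GroundTruthSpec(n_genes=20, n_samples_per_group=100, seed=100 + seed)
            m, _ = simulate_ggm_expression(spec)
            net = build_coexpression_network(m, "untreated", alpha=0.01)
            rates.append(net.n_edges / (20 * 19 / 2))
        assert np.mean(rates) <= 0.015  # approx alpha, not above it systematically

    def test_edge_keys_sorted_and_weights_in_range(self):
        spec = GroundTruthSpec(
            n_genes=10, true_edges=frozenset({(0, 5), (2, 7)}),
            partial_correlation_strength=0.6, n_samples_per_group=200, seed=0,
        )
        m, _ = simulate_ggm_expression(spec)
        net = build_coexpression_network(m, "untreated")
        for (a, b), w in net.edges.items():
            assert (a, b) == tuple(sorted((a, b)))
            assert 0 < w <= 1

    def test_zeroth_order_weight_rule(self):
        spec = GroundTruthSpec(
            n_genes=5, true_edges=frozenset({(0, 1)}),
            partial_correlation_strength=0.7, n_samples_per_group=300, seed=2,
        )
        m, _ = simulate_ggm_expression(spec)
        weakest = build_coexpression_network(m, "untreated", weight_rule="weakest_partial")
        zeroth = build_coexpression_network(m, "untreated", weight_rule="zeroth_order")
        assert set(weakest.edges) == set(zeroth.edges)
        r = np.corrcoef(stats.rankdata(m.group_values("untreated"), axis=1))
        assert zeroth.edges[("G1", "G2")] == pytest.approx(abs(r[0, 1]))

    def test_preconditions(self):
        m = one_group_matrix(np.random.default_rng(0).standard_normal((2, 10)))
        with pytest.raises(ValueError, match="3 non-constant genes"):
            build_coexpression_network(m, "grp")
        m = one_group_matrix(np.random.default_rng(0).standard_normal((5, 4)))
        with pytest.raises(ValueError, match="at least 5 samples"):
            build_coexpression_network(m, "grp")
        m = one_group_matrix(np.random.default_rng(0).standard_normal((5, 10)))
        with pytest.raises(ValueError, match="weight_rule"):
            build_coexpression_network(m, "grp", weight_rule="bogus")

    def test_conditioner_cap_reduces_work_but_keeps_strong_edges(self):
        spec = GroundTruthSpec(
            n_genes=20, true_edges=frozenset({(0, 1)}),
            partial_correlation_strength=0.7, n_samples_per_group=300, seed=5,
        )
        m, _ = simulate_ggm_expression(spec)
        net = build_coexpression_network(m, "untreated", max_conditioners=5)
        assert ("G1", "G2") in net.edges


class TestPermutationNull:
    def test_add_one_rule_when_observed_exceeds_all(self):
        spec = GroundTruthSpec(
            n_genes=10, true_edges=frozenset({(i, i + 1) for i in range(8)}),
            partial_correlation_strength=0.6, n_samples_per_group=150, seed=3,
        )
        m, _ = simulate_ggm_expression(spec)
        null = permutation_null(m, "untreated", n_replicates=50, seed=17)
        assert null.observed_count > max(null.replicate_counts)
        assert null.empirical_p == pytest.approx(1 / 51)

    def test_replicate_count_and_determinism(self):
        spec = GroundTruthSpec(n_genes=6, n_samples_per_group=30, seed=4)
        m, _ = simulate_ggm_expression(spec)
        n1 = permutation_null(m, "untreated", n_replicates=20, seed=9)
        n2 = permutation_null(m, "untreated", n_replicates=20, seed=9)
        assert n1.replicate_counts == n2.replicate_counts
        assert len(n1.replicate_counts) == 20

    def test_invalid_replicates_rejected(self):
        spec = GroundTruthSpec(n_genes=6, n_samples_per_group=30, seed=4)
        m, _ = simulate_ggm_expression(spec)
        with pytest.raises(ValueError, match="n_replicates"):
            permutation_null(m, "untreated", n_replicates=0)
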