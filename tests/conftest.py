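"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from influnet.coexpr import CoexpressionNetwork


def random_weighted_network(rng: np.random.Generator, max_nodes: int = 50) -> CoexpressionNetwork:
    """Random undirected weighted graph with weights in (0, 1]."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"N{i:02d}" for i in range(n)]
    p = rng.uniform(0.05, 0.6)
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(nodes[i], nodes[j])] = float(1.0 - rng.random())  # (0, 1]
    return CoexpressionNetwork(nodes=nodes, edges=edges)


@pytest.fixture
def two_leaf_star() -> CoexpressionNetwork:
    """Star A-B (0.8), A-C (0.4): the canonical worked example."""
    return CoexpressionNetwork(
        nodes=["A", "B", "C"], edges={("A", "B"): 0.8, ("A", "C"): 0.4}
    )


@pytest.fixture
def equal_triangle() -> CoexpressionNetwork:
    return CoexpressionNetwork(
        nodes=["A", "B", "C"],
        edges={("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5},
    )


@pytest.fixture
def expression_tsv(tmp_path):
    """A tiny valid expression TSV plus its group map."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tS1\tS2\tS3\n"
        "G1\t1.5\t2.0\t0.25\n"
        "G2\t-0.5\t3.25\t1.0\n"
    )
    groups = tmp_path / "groups.tsv"
    groups.write_text("sample_id\tgroup\nS1\tday0\nS2\tday0\nS3\tday90\n")
    return path, groups
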