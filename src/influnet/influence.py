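"""Directed influence networks and cumulative influence scores.

An undirected weighted coexpression network is converted into a directed
weighted network by asking, for every node B, what fraction of B's total
edge weight each neighbor contributes:

    Influence(A, B) = w(A, B) / sum over neighbors X of B of w(B, X)

Every undirected edge therefore yields two directed edges with, in
general, different weights, encoding the asymmetry of the relationship:
a node whose partner has no other neighbors influences it completely
(weight 1), while a node connected to a well-connected partner holds
only a small share of that partner's dependence structure.

Because the denominator runs over *all* of B's neighbors (including A),
the incoming influences of every non-isolated node sum to exactly 1 —
each node distributes one unit of "being influenced" among its
neighbors. Summing a node's outgoing weights gives its cumulative
influence score

    Influence(A) = sum over X of Influence(A, X),

which totals the number of non-isolated nodes across the network. The
score is invariant to any positive rescaling of the input edge weights.
This is a one-step proportion, not an iterative fixed point: no
PageRank-style propagation is involved.
"""

from __future__ import annotations

import numpy as np

from dataclasses import dataclass, field

from .coexpr import CoexpressionNetwork

__all__ = [
    "InfluenceNetwork",
    "InfluenceScoreTable",
    "build_influence_network",
    "cumulative_influence",
    "select_influential",
    "tukey_upper_outliers",
]


@dataclass
class InfluenceNetwork:
    """Directed weighted graph; ``directed_edges[(a, b)]`` = Influence(a, b)."""

    nodes: list[str]
    directed_edges: dict

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node IDs")
        for (a, b), w in self.directed_edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            if not (0 < w <= 1 + 1e-9):
                raise ValueError(f"influence weight {w} outside (0, 1]")
            if (b, a) not in self.directed_edges:
                raise ValueError(f"edge ({a!r}, {b!r}) lacks its reverse edge")

    def out_edges(self, node: str) -> dict:
        return {(a, b): w for (a, b), w in self.directed_edges.items() if a == node}

    def in_weight_sum(self, node: str) -> float:
        return sum(w for (a, b), w in self.directed_edges.items() if b == node)

    def to_networkx(self, length: str | None = None):
        """As a networkx DiGraph; ``length`` optionally adds an edge
        attribute ``1/weight`` (``"reciprocal"``) or ``weight``
        (``"as_distance"``) for shortest-path algorithms."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.directed_edges.items():
            attrs = {"weight": w}
            if length == "reciprocal":
                attrs["length"] = 1.0 / w
            elif length == "as_distance":
                attrs["length"] = w
            elif length is not None:
                raise ValueError(f"unknown length mode {length!r}")
            g.add_edge(a, b, **attrs)
        return g


@dataclass
class InfluenceScoreTable:
    """Per-gene cumulative influence with outlier flags and ranks.

    Rank 1 is the highest score; ties break by ascending gene ID.
    Isolated genes are present with score 0.
    """

    gene_ids: list[str]
    influence_score: np.ndarray
    outlier_flag: np.ndarray
    rank: np.ndarray

    def __post_init__(self) -> None:
        self.influence_score = np.asarray(self.influence_score, dtype=float)
        self.outlier_flag = np.asarray(self.outlier_flag, dtype=bool)
        self.rank = np.asarray(self.rank, dtype=int)

    def score_of(self, gene: str, default: float = 0.0) -> float:
        try:
            return float(self.influence_score[self.gene_ids.index(gene)])
        except ValueError:
            return default

    def top(self, k: int) -> list[str]:
        if k > len(self.gene_ids):
            raise ValueError(f"k = {k} exceeds gene count {len(self.gene_ids)}")
        order = np.argsort(self.rank)
        return [self.gene_ids[i] for i in order[:k]]

    def outliers(self) -> list[str]:
        flagged = [g for g, f in zip(self.gene_ids, self.outlier_flag) if f]
        return sorted(flagged, key=lambda g: (self.rank[self.gene_ids.index(g)], g))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "influence": self.influence_score,
                "is_outlier": self.outlier_flag,
                "rank": self.rank,
            }
        )


def build_influence_network(net: CoexpressionNetwork) -> InfluenceNetwork:
    """Convert an undirected weighted network into its influence network.

    For each undirected edge {A, B} two directed edges are created:
    A->B weighted by w(A,B) / (total edge weight incident to B), and the
    mirror image for B->A. Isolated nodes carry no edges but remain in
    the node set.
    """
    total: dict[str, float] = {node: 0.0 for node in net.nodes}
    for (a, b), w in net.edges.items():
        total[a] += w
        total[b] += w
    directed: dict[tuple[str, str], float] = {}
    for (a, b), w in net.edges.items():
        directed[(a, b)] = w / total[b]
        directed[(b, a)] = w / total[a]
    return InfluenceNetwork(nodes=list(net.nodes), directed_edges=directed)


def cumulative_influence(inet: InfluenceNetwork) -> InfluenceScoreTable:
    """Sum each node's outgoing influence weights (its influence score)."""
    scores = {node: 0.0 for node in inet.nodes}
    for (a, _b), w in inet.directed_edges.items():
        scores[a] += w
    gene_ids = list(inet.nodes)
    values = np.array([scores[g] for g in gene_ids])
    order = sorted(range(len(gene_ids)), key=lambda i: (-values[i], gene_ids[i]))
    rank = np.empty(len(gene_ids), dtype=int)
    for pos, idx in enumerate(order, start=1):
        rank[idx] = pos
    return InfluenceScoreTable(
        gene_ids=gene_ids,
        influence_score=values,
        outlier_flag=tukey_upper_outliers(values),
        rank=rank,
    )


def tukey_upper_outliers(values: np.ndarray) -> np.ndarray:
    """Boxplot rule: flag values above Q3 + 1.5 * IQR.

    Quartiles use linear interpolation (the common boxplot convention),
    pinned here for reproducibility.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.zeros(0, dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return values > fence


def select_influential(
    table: InfluenceScoreTable, mode: str = "outlier", k: int | None = None
) -> list[str]:
    """Pick the influential genes, ordered by rank.

    ``mode="outlier"`` returns the upper-Tukey-fence outliers by score;
    ``mode="top_k"`` returns the ``k`` highest-ranked genes.
    """
    if not table.gene_ids:
        raise ValueError("empty score table")
    if mode == "outlier":
        return table.outliers()
    if mode == "top_k":
        if k is None:
            raise ValueError("top_k mode requires k")
        return table.top(k)
    raise ValueError(f"unknown selection mode {mode!r}")
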