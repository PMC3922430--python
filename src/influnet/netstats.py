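"""Comparison centralities and essentiality-enrichment statistics.

Out-degree and weighted directed betweenness are the two classic
centrality baselines against which influence scores are compared: hubs
(degree outliers) and bottlenecks (betweenness outliers) are the usual
network-biology candidates for essential genes.

Shortest-path algorithms interpret edge weights as *lengths*, whereas
influence weights measure *strength*. The default ``reciprocal`` mode
therefore uses 1/influence as the edge length, so strong edges are
short; ``as_distance`` passes the weights through unchanged for
compatibility with toolchains that feed strengths to a shortest-path
routine directly.

Essentiality is called from a gene x cell-line p-value table: a gene is
essential if its knockdown statistic reaches p <= 0.05 in at least one
cell line. Enrichment of essential genes in a selected set is scored
with the upper-tail cumulative binomial against the background
proportion, and two selected sets are compared with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .expression_io import EssentialityTable
from .influence import InfluenceNetwork, tukey_upper_outliers

__all__ = [
    "CentralityTable",
    "EnrichmentResult",
    "out_degree",
    "weighted_betweenness",
    "centrality_table",
    "call_hubs_bottlenecks",
    "essential_gene_set",
    "binomial_enrichment",
    "compare_proportions_fisher",
    "enrichment_vs_background",
]


@dataclass
class CentralityTable:
    """Per-gene out-degree and betweenness with hub/bottleneck flags."""

    gene_ids: list[str]
    out_degree: np.ndarray
    betweenness: np.ndarray
    hub_flag: np.ndarray
    bottleneck_flag: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "out_degree": self.out_degree,
                "betweenness": self.betweenness,
                "is_hub": self.hub_flag,
                "is_bottleneck": self.bottleneck_flag,
            }
        )


@dataclass
class EnrichmentResult:
    """Essential-gene enrichment of a selected gene set.

    ``binomial_p`` is the upper-tail P(X >= k) for X ~ Binomial(n, p0)
    with p0 the background essential proportion; ``fisher_p`` is set for
    two-set proportion comparisons.
    """

    set_size: int
    essential_in_set: int
    background_size: int
    essential_in_background: int
    background_proportion: float
    binomial_p: float
    fisher_p: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.essential_in_set <= self.set_size):
            raise ValueError("essential_in_set must lie in [0, set_size]")
        if not (0 <= self.essential_in_background <= self.background_size):
            raise ValueError("essential_in_background must lie in [0, background_size]")


def out_degree(inet: InfluenceNetwork) -> dict:
    """Outgoing-edge count per node.

    Every node pair carries two opposite directed edges, so out-degree
    equals the undirected degree in the source coexpression network.
    """
    counts = {node: 0 for node in inet.nodes}
    for (a, _b) in inet.directed_edges:
        counts[a] += 1
    return counts


def weighted_betweenness(inet: InfluenceNetwork, weight_mode: str = "reciprocal") -> dict:
    """Weighted directed betweenness per node (endpoints excluded).

    Shortest paths are computed on edge lengths 1/influence
    (``reciprocal``, default) or on the influence weights themselves
    (``as_distance``). Equal-length path multiplicity is split
    fractionally, the standard betweenness convention.
    """
    if weight_mode not in ("reciprocal", "as_distance"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    g = inet.to_networkx(length=weight_mode)
    return dict(nx.betweenness_centrality(g, weight="length", normalized=False))


def centrality_table(inet: InfluenceNetwork, weight_mode: str = "reciprocal") -> CentralityTable:
    """Combined degree/betweenness table with Tukey outlier flags."""
    degrees = out_degree(inet)
    between = weighted_betweenness(inet, weight_mode)
    gene_ids = list(inet.nodes)
    deg = np.array([degrees[g] for g in gene_ids], dtype=int)
    btw = np.array([between[g] for g in gene_ids], dtype=float)
    return CentralityTable(
        gene_ids=gene_ids,
        out_degree=deg,
        betweenness=btw,
        hub_flag=tukey_upper_outliers(deg),
        bottleneck_flag=tukey_upper_outliers(btw),
    )


def _select_by(gene_ids, values, flags, mode: str, k: int | None) -> list[str]:
    if mode == "outlier":
        chosen = [g for g, f in zip(gene_ids, flags) if f]
    elif mode == "top_k":
        if k is None:
            raise ValueError("top_k mode requires k")
        if k > len(gene_ids):
            raise ValueError(f"k = {k} exceeds gene count {len(gene_ids)}")
        order = sorted(range(len(gene_ids)), key=lambda i: (-values[i], gene_ids[i]))
        chosen = [gene_ids[i] for i in order[:k]]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return sorted(chosen, key=lambda g: (-values[gene_ids.index(g)], g))


def call_hubs_bottlenecks(
    ct: CentralityTable, mode: str = "outlier", k: int | None = None
) -> tuple[list[str], list[str]]:
    """Hub (degree) and bottleneck (betweenness) gene sets.

    Uses the same Tukey-fence/top-k selection rule as influential-gene
    selection, applied to the degree and betweenness columns.
    """
    if not ct.gene_ids:
        raise ValueError("empty centrality table")
    hubs = _select_by(ct.gene_ids, ct.out_degree, ct.hub_flag, mode, k)
    bottlenecks = _select_by(ct.gene_ids, ct.betweenness, ct.bottleneck_flag, mode, k)
    return hubs, bottlenecks


def essential_gene_set(table: EssentialityTable, p_threshold: float = 0.05) -> set:
    """Genes with p <= threshold in at least one cell line (inclusive).

    Missing entries are ignored; a gene with only missing values is
    excluded with a warning.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must lie in (0, 1]")
    finite = np.isfinite(table.pvalues)
    all_missing = ~finite.any(axis=1)
    if all_missing.any():
        missing_genes = [g for g, m in zip(table.gene_ids, all_missing) if m]
        warnings.warn(
            f"{len(missing_genes)} gene(s) with no p-values excluded from "
            f"essentiality calls: {missing_genes[:5]}",
            RuntimeWarning,
            stacklevel=2,
        )
    hit = np.where(finite, table.pvalues <= p_threshold, False).any(axis=1)
    return {g for g, h in zip(table.gene_ids, hit) if h}


def binomial_enrichment(k: int, n: int, p0: float) -> EnrichmentResult:
    """Upper-tail cumulative binomial p-value P(X >= k), X ~ Bin(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 <= p0 <= 1):
        raise ValueError("p0 must lie in [0, 1]")
    p = 1.0 if k == 0 else float(stats.binom.sf(k - 1, n, p0))
    return EnrichmentResult(
        set_size=n,
        essential_in_set=k,
        background_size=n,
        essential_in_background=int(round(n * p0)),
        background_proportion=p0,
        binomial_p=p,
    )


def compare_proportions_fisher(k1: int, n1: int, k2: int, n2: int) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the 2x2 table [[k1, n1-k1], [k2, n2-k2]].

    Two-sidedness follows the minimum-likelihood rule: the p-value sums
    the probabilities of all hypergeometric tables no more likely than
    the observed one.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("invalid counts")
    _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    return EnrichmentResult(
        set_size=n1,
        essential_in_set=k1,
        background_size=n2,
        essential_in_background=k2,
        background_proportion=k2 / n2 if n2 else 0.0,
        binomial_p=float("nan"),
        fisher_p=float(p),
    )


def enrichment_vs_background(
    selected: set, network_genes: set, essential: set
) -> EnrichmentResult:
    """Binomial enrichment of a selected set against the rest of the network.

    The background proportion is the essential fraction among the
    network's genes *excluding* the tested set, contrasting the selected
    genes with the non-selected genes of the same network.
    """
    selected = set(selected)
    if not selected <= set(network_genes):
        raise ValueError("selected genes must belong to the network")
    background = set(network_genes) - selected
    if not background:
        raise ValueError("background is empty")
    k = len(selected & essential)
    bg_k = len(background & essential)
    p0 = bg_k / len(background)
    result = binomial_enrichment(k, len(selected), p0)
    return EnrichmentResult(
        set_size=len(selected),
        essential_in_set=k,
        background_size=len(background),
        essential_in_background=bg_k,
        background_proportion=p0,
        binomial_p=result.binomial_p,
    )
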