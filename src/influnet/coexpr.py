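"""Coexpression networks from first-order partial Spearman correlations.

An edge joins two genes when their rank (Spearman) correlation is
significant *and stays significant after conditioning on every other
gene in the set, one at a time* (the first-order partial-correlation
screen). Conditioning removes correlations that arise solely through a
common regulator: if gene k drives both i and j, the i-j correlation
vanishes once k is partialled out, and the screen drops the i-j edge.

Significance of a (partial) correlation r with k conditioning variables
is assessed with the Fisher z-transform: z = atanh(r) is approximately
normal with standard error 1 / sqrt(n - k - 3), giving a two-sided test.
The smallest usable group is therefore n = 5 (one conditioner leaves
n - 4 = 1).

Edge weights are the absolute partial correlation at the *weakest*
surviving conditioner (the one with the largest partial p-value) — the
most conservative of the surviving values. ``weight_rule="zeroth_order"``
swaps in the plain |Spearman correlation| instead.

The observed edge count is validated by a permutation null: each
replicate independently permutes every gene's values across the group's
samples, destroying all gene-gene dependence while preserving marginals,
and the full edge criterion is re-applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression_io import ExpressionMatrix

__all__ = [
    "CoexpressionNetwork",
    "NullDistribution",
    "rank_transform",
    "partial_correlation_first_order",
    "build_coexpression_network",
    "permutation_null",
]

_CLIP = 1.0 - 1e-15  # |r| = 1 maps to p = 0 without atanh overflow


@dataclass
class CoexpressionNetwork:
    """Undirected weighted graph of significant partial correlations.

    ``edges`` maps sorted gene-ID pairs to weights in (0, 1] (absolute
    partial correlation). ``dropped_genes`` lists genes excluded for zero
    rank variance.
    """

    nodes: list[str]
    edges: dict
    alpha: float | None = None
    n_samples: int | None = None
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node IDs")
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"edge key ({a!r}, {b!r}) is not sorted")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            if not (0 < w <= 1 + 1e-12):
                raise ValueError(f"edge weight {w} outside (0, 1] for ({a!r}, {b!r})")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


@dataclass
class NullDistribution:
    """Permutation null for the significant-edge count.

    ``empirical_p`` uses the add-one rule
    (1 + #{replicates >= observed}) / (1 + n_replicates), so it can never
    be exactly zero.
    """

    replicate_counts: list[int]
    observed_count: int
    n_replicates: int

    @property
    def empirical_p(self) -> float:
        exceed = sum(1 for c in self.replicate_counts if c >= self.observed_count)
        return (1 + exceed) / (1 + self.n_replicates)


def rank_transform(matrix: ExpressionMatrix, group: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-gene average ranks across one group's samples.

    Returns ``(ranks, kept_gene_ids, dropped_gene_ids)``; constant genes
    (zero rank variance) are excluded with a warning, since no
    correlation is defined for them.
    """
    values = matrix.group_values(group)
    ranks = stats.rankdata(values, axis=1)
    constant = np.all(values == values[:, [0]], axis=1)
    kept = [g for g, c in zip(matrix.gene_ids, constant) if not c]
    dropped = [g for g, c in zip(matrix.gene_ids, constant) if c]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} constant gene(s) from network construction: "
            f"{dropped[:5]}",
            RuntimeWarning,
            stacklevel=2,
        )
    return ranks[~constant], kept, dropped


def partial_correlation_first_order(r_ij: float, r_ik: float, r_jk: float) -> float:
    """First-order partial correlation of i and j given k.

    pcor = (r_ij - r_ik * r_jk) / sqrt((1 - r_ik^2) * (1 - r_jk^2)).
    Undefined when either conditioning correlation is +/-1.
    """
    for r in (r_ij, r_ik, r_jk):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    denom_sq = (1.0 - r_ik**2) * (1.0 - r_jk**2)
    if denom_sq <= 0:
        raise ValueError("partial correlation undefined: a conditioning correlation is +/-1")
    return (r_ij - r_ik * r_jk) / math.sqrt(denom_sq)


def _fisher_z_pvalue(r: np.ndarray, n: int, n_conditioners: int) -> np.ndarray:
    """Two-sided p-value for (partial) correlations via Fisher's z."""
    dof = n - n_conditioners - 3
    if dof < 1:
        raise ValueError(f"need n >= {n_conditioners + 4} samples, got {n}")
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return 2.0 * stats.norm.sf(np.abs(z) * math.sqrt(dof))


def _edge_screen(
    ranks: np.ndarray,
    n: int,
    alpha: float,
    weight_rule: str,
    conditioner_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised all-pairs first-order screen.

    Returns (edge boolean matrix, weight matrix), upper-triangular
    semantics (symmetric matrices returned for convenience).
    """
    g = ranks.shape[0]
    r = np.corrcoef(ranks)
    np.fill_diagonal(r, 1.0)
    p0 = _fisher_z_pvalue(r, n, 0)
    significant = p0 <= alpha
    np.fill_diagonal(significant, False)

    # running maximum partial p-value and the |pcor| observed there
    worst_p = np.full((g, g), -1.0)
    worst_w = np.abs(r).copy()  # fallback weight when no conditioner is usable
    any_skipped = False
    ks = range(g) if conditioner_indices is None else conditioner_indices
    for k in ks:
        rk = r[:, k]
        var_k = 1.0 - rk**2
        usable = var_k > 1e-14  # conditioning correlation strictly inside (-1, 1)
        others = np.ones(g, dtype=bool)
        others[k] = False  # r[k, k] = 1 is not a degenerate conditioner
        if not usable[others].all():
            any_skipped = True
        denom = np.sqrt(np.outer(var_k, var_k))
        with np.errstate(divide="ignore", invalid="ignore"):
            pcor = (r - np.outer(rk, rk)) / denom
        pk = _fisher_z_pvalue(np.nan_to_num(pcor), n, 1)
        # pairs for which k is a valid conditioner
        valid = np.outer(usable, usable).copy()
        valid[k, :] = False
        valid[:, k] = False
        significant &= ~valid | (pk <= alpha)
        update = valid & (pk > worst_p)
        worst_p[update] = pk[update]
        worst_w[update] = np.abs(pcor[update])
    if any_skipped:
        warnings.warn(
            "some conditioning genes were skipped (|r| = 1 with a pair member)",
            RuntimeWarning,
            stacklevel=3,
        )
    weights = np.abs(r) if weight_rule == "zeroth_order" else worst_w
    return significant, weights


def build_coexpression_network(
    matrix: ExpressionMatrix,
    group: str,
    alpha: float = 0.01,
    weight_rule: str = "weakest_partial",
    max_conditioners: int | None = None,
    conditioner_seed: int = 0,
) -> CoexpressionNetwork:
    """Build the coexpression network for one sample group.

    Parameters
    ----------
    matrix, group:
        Expression data and the group whose samples are used.
    alpha:
        Two-sided significance threshold applied to the marginal and to
        every first-order partial correlation.
    weight_rule:
        ``"weakest_partial"`` (default) weights each edge by the absolute
        partial correlation at the largest-p conditioner;
        ``"zeroth_order"`` uses the plain |Spearman correlation|.
    max_conditioners:
        Optional cap on the number of conditioning genes (a random subset
        drawn with ``conditioner_seed``) to tame the O(G^3) cost on large
        gene sets. Off by default.
    """
    if weight_rule not in ("weakest_partial", "zeroth_order"):
        raise ValueError(f"unknown weight_rule {weight_rule!r}")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    ranks, kept, dropped = rank_transform(matrix, group)
    if len(kept) < 3:
        raise ValueError("need at least 3 non-constant genes")
    n = ranks.shape[1]
    if n < 5:
        raise ValueError("need at least 5 samples in the group")
    cond = None
    if max_conditioners is not None and max_conditioners < len(kept):
        rng = np.random.default_rng(conditioner_seed)
        cond = rng.choice(len(kept), size=max_conditioners, replace=False)
    edge_mask, weights = _edge_screen(ranks, n, alpha, weight_rule, cond)
    edges = {}
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            if edge_mask[i, j]:
                w = float(min(weights[i, j], 1.0))
                if w > 0:
                    edges[tuple(sorted((kept[i], kept[j])))] = w
    return CoexpressionNetwork(
        nodes=list(kept),
        edges=edges,
        alpha=alpha,
        n_samples=n,
        dropped_genes=dropped,
    )


def _count_edges(ranks: np.ndarray, n: int, alpha: float) -> int:
    if ranks.shape[0] < 2:
        return 0
    edge_mask, _ = _edge_screen(ranks, n, alpha, "weakest_partial")
    return int(np.triu(edge_mask, 1).sum())


def permutation_null(
    matrix: ExpressionMatrix,
    group: str,
    alpha: float = 0.01,
    n_replicates: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Permutation null distribution of the significant-edge count.

    Each replicate permutes every gene's expression values independently
    across the group's samples and recounts significant pairs under the
    identical edge criterion. Replicate r uses
    ``numpy.random.default_rng(seed + 1 + r)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    observed_net = build_coexpression_network(matrix, group, alpha=alpha)
    observed = observed_net.n_edges
    values = matrix.group_values(group)
    n = values.shape[1]
    counts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for rep in range(n_replicates):
            rng = np.random.default_rng(seed + 1 + rep)
            permuted = np.empty_like(values)
            for gi in range(values.shape[0]):
                permuted[gi] = values[gi, rng.permutation(n)]
            ranks = stats.rankdata(permuted, axis=1)
            constant = np.all(permuted == permuted[:, [0]], axis=1)
            counts.append(_count_edges(ranks[~constant], n, alpha))
    return NullDistribution(
        replicate_counts=counts, observed_count=observed, n_replicates=n_replicates
    )
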