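"""Synthetic expression data with a known conditional-dependence graph.

Samples are drawn from a Gaussian graphical model (GGM): a zero-mean
multivariate normal whose precision matrix carries nonzero off-diagonal
entries exactly on a chosen edge set, so the true direct (partial)
dependencies are known by construction. On top of the Gaussian draw the
generator supports

* a mean shift for a chosen set of differentially expressed genes in the
  "treated" group (two-group design), mirroring a before/after-treatment
  contrast;
* a strictly monotone marginal transform (``exponential``), which leaves
  rank-based downstream analysis invariant and motivates the use of
  Spearman rather than Pearson correlation;
* a three-group mode with group-specific edge sets, emulating network
  rewiring across treatment time points;
* a planted-essential-gene p-value table shaped like a pooled shRNA
  screen readout.

The precision matrix starts from the identity, places
``+/- partial_correlation_strength`` on the true edges (signs drawn from
the seed), and raises the diagonal of any row whose off-diagonal sum
would break strict diagonal dominance. This guarantees positive
definiteness without rejection sampling; the price is that the
*effective* partial correlation of edges touching high-degree nodes
shrinks below the nominal strength (by 1/sqrt of the inflated diagonal),
while edges between low-degree nodes keep it exactly.

All randomness descends from the single integer ``seed`` via
``numpy.random.SeedSequence(seed).spawn``: child 0 drives edge signs,
child 1 the expression draw, child 2 the essentiality table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression_io import EssentialityTable, ExpressionMatrix

__all__ = [
    "GroundTruthSpec",
    "precision_matrix",
    "simulate_ggm_expression",
    "simulate_multigroup_expression",
    "simulate_essentiality_table",
]

_DOMINANCE_MARGIN = 0.95  # max allowed off-diagonal row sum (diagonal = 1)


@dataclass
class GroundTruthSpec:
    """Ground truth for one synthetic data set.

    ``true_edges`` are unordered pairs of gene indices in
    ``range(n_genes)``; ``de_genes`` and ``essential_genes`` are gene
    indices as well. ``n_samples_per_group`` defaults to 58, the size of
    a typical neoadjuvant trial arm; ``de_effect_size`` is a log-scale
    mean shift (1.0 = about a two-fold change on a log2 scale).
    """

    n_genes: int
    true_edges: frozenset = frozenset()
    partial_correlation_strength: float = 0.5
    n_samples_per_group: int = 58
    de_genes: frozenset = frozenset()
    de_effect_size: float = 1.0
    marginal_transform: str = "identity"
    essential_genes: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 < self.partial_correlation_strength < 1):
            raise ValueError("partial_correlation_strength must lie in (0, 1)")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be positive")
        if self.marginal_transform not in ("identity", "exponential"):
            raise ValueError(f"unknown marginal_transform {self.marginal_transform!r}")
        edges = set()
        for pair in self.true_edges:
            i, j = pair
            if i == j:
                raise ValueError(f"self-loop edge ({i}, {j})")
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes):
                raise ValueError(f"edge ({i}, {j}) references an invalid gene index")
            edges.add((min(i, j), max(i, j)))
        self.true_edges = frozenset(edges)
        for name, genes in (("de_genes", self.de_genes), ("essential_genes", self.essential_genes)):
            bad = [g for g in genes if not (0 <= g < self.n_genes)]
            if bad:
                raise ValueError(f"{name} contains invalid gene indices {bad[:5]}")
        self.de_genes = frozenset(self.de_genes)
        self.essential_genes = frozenset(self.essential_genes)

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genes)]

    def true_edge_ids(self) -> frozenset:
        ids = self.gene_ids()
        return frozenset(tuple(sorted((ids[i], ids[j]))) for i, j in self.true_edges)


def _seed_children(seed: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(3)


def precision_matrix(
    n_genes: int,
    edges,
    strength: float,
    sign_rng: np.random.Generator,
) -> np.ndarray:
    """Build a symmetric positive-definite precision matrix for ``edges``.

    Unit diagonal with ``+/- strength`` on edges (random signs); any row
    whose off-diagonal absolute sum reaches the dominance margin has its
    diagonal raised to ``row_sum / margin``, making every row strictly
    diagonally dominant (hence SPD by Gershgorin). Inflating the diagonal
    only where needed keeps the effective partial correlation of an edge
    local to its two endpoints — a single high-degree node does not
    weaken edges elsewhere in the graph.
    """
    omega = np.eye(n_genes)
    for i, j in sorted(edges):
        sign = 1.0 if sign_rng.random() < 0.5 else -1.0
        omega[i, j] = omega[j, i] = sign * strength
    off = np.abs(omega).sum(axis=1) - np.diag(omega)
    np.fill_diagonal(omega, np.maximum(1.0, off / _DOMINANCE_MARGIN))
    # Gershgorin guarantees PD; assert cheaply rather than trust silently.
    if np.linalg.eigvalsh(omega)[0] <= 0:
        raise RuntimeError("precision matrix construction failed to be positive definite")
    return omega


def _draw_mvn(omega: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n samples (columns) from N(0, inv(omega))."""
    cov = np.linalg.inv(omega)
    cov = (cov + cov.T) / 2.0
    return rng.multivariate_normal(np.zeros(omega.shape[0]), cov, size=n, method="cholesky").T


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return values
    if transform == "exponential":
        return np.exp(values)
    raise ValueError(f"unknown marginal_transform {transform!r}")


def simulate_ggm_expression(spec: GroundTruthSpec) -> tuple[ExpressionMatrix, GroundTruthSpec]:
    """Two-group (untreated/treated) expression draw from the GGM.

    Both groups share the dependence graph; genes in ``spec.de_genes``
    are shifted by ``spec.de_effect_size`` in the treated group. Same
    spec and seed always yield an identical matrix.
    """
    children = _seed_children(spec.seed)
    sign_rng = np.random.default_rng(children[0])
    draw_rng = np.random.default_rng(children[1])
    omega = precision_matrix(
        spec.n_genes, spec.true_edges, spec.partial_correlation_strength, sign_rng
    )
    n = spec.n_samples_per_group
    values = _draw_mvn(omega, 2 * n, draw_rng)
    if spec.de_genes:
        de = sorted(spec.de_genes)
        values[np.ix_(de, range(n, 2 * n))] += spec.de_effect_size
    values = _apply_transform(values, spec.marginal_transform)
    sample_ids = [f"S{i + 1}" for i in range(2 * n)]
    groups = {s: ("untreated" if i < n else "treated") for i, s in enumerate(sample_ids)}
    matrix = ExpressionMatrix(
        gene_ids=spec.gene_ids(), sample_ids=sample_ids, values=values, group_labels=groups
    )
    return matrix, spec


def simulate_multigroup_expression(
    n_genes: int,
    group_edges: dict,
    strength: float,
    n_samples_per_group: int,
    seed: int,
    marginal_transform: str = "identity",
) -> ExpressionMatrix:
    """Multi-group draw where each group has its own dependence graph.

    ``group_edges`` maps group name (e.g. ``day0``/``day14``/``day90``)
    to that group's edge set. Emulates treatment-induced network
    rewiring: the gene universe is fixed, the direct-dependence structure
    changes between conditions.
    """
    if n_samples_per_group < 1:
        raise ValueError("n_samples_per_group must be positive")
    children = np.random.SeedSequence(seed).spawn(2 * len(group_edges))
    gene_ids = [f"G{i + 1}" for i in range(n_genes)]
    blocks = []
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    for g_idx, (group, edges) in enumerate(group_edges.items()):
        # validate via the spec's own invariants
        spec = GroundTruthSpec(
            n_genes=n_genes, true_edges=frozenset(map(tuple, edges)),
            partial_correlation_strength=strength, n_samples_per_group=n_samples_per_group,
        )
        sign_rng = np.random.default_rng(children[2 * g_idx])
        draw_rng = np.random.default_rng(children[2 * g_idx + 1])
        omega = precision_matrix(n_genes, spec.true_edges, strength, sign_rng)
        block = _draw_mvn(omega, n_samples_per_group, draw_rng)
        blocks.append(_apply_transform(block, marginal_transform))
        for i in range(n_samples_per_group):
            sid = f"{group}_S{i + 1}"
            sample_ids.append(sid)
            labels[sid] = group
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.hstack(blocks),
        group_labels=labels,
    )


def simulate_essentiality_table(spec: GroundTruthSpec, n_celllines: int) -> EssentialityTable:
    """Planted-essential-gene p-value table (one column per cell line).

    Every planted essential gene is guaranteed a p-value <= 0.05 in at
    least one cell line (one line drawn uniformly, p ~ U(0, 0.05]); all
    other entries are uniform on (0.05, 1], so non-essential genes can
    never be called essential at the 0.05-in-one-line rule.
    """
    if n_celllines < 1:
        raise ValueError("n_celllines must be >= 1")
    rng = np.random.default_rng(_seed_children(spec.seed)[2])
    # (1 - U[0,1)) keeps draws strictly above the lower bound
    pvals = 0.05 + (1.0 - rng.random((spec.n_genes, n_celllines))) * 0.95
    for g in sorted(spec.essential_genes):
        line = int(rng.integers(n_celllines))
        pvals[g, line] = (1.0 - rng.random()) * 0.05
    return EssentialityTable(
        gene_ids=spec.gene_ids(),
        cellline_ids=[f"CL{i + 1}" for i in range(n_celllines)],
        pvalues=pvals,
    )
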