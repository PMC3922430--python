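"""Reading, writing and validation of the package's file formats.

All on-disk formats are plain TSV:

* expression matrix — header row of sample IDs, first column gene IDs,
  numeric log-scale expression values;
* group map — two columns ``sample_id``, ``group`` with a header row;
* essentiality table — first column gene IDs, remaining columns per
  cell-line p-values in [0, 1] (empty cells are missing);
* edge lists — ``source``, ``target``, ``weight`` (one row per undirected
  edge; two rows per node pair for directed influence networks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "EssentialityTable",
    "read_expression_matrix",
    "read_group_map",
    "read_essentiality_table",
    "write_expression_matrix",
    "write_group_map",
    "write_essentiality_table",
    "write_edge_list",
    "read_undirected_edge_list",
    "read_directed_edge_list",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix with group labels.

    Parameters
    ----------
    gene_ids:
        Unique gene identifiers (opaque strings; Entrez IDs or symbols).
    sample_ids:
        Unique sample identifiers, one per matrix column.
    values:
        ``(len(gene_ids), len(sample_ids))`` float array; all finite.
    group_labels:
        Mapping ``sample_id -> group name`` (e.g. ``"day0"``). May label
        only a subset of samples, but never a sample absent from
        ``sample_ids``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene ID")
        _check_unique(self.sample_ids, "sample ID")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            idx = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite expression value at "
                f"gene {self.gene_ids[idx[0]]!r}, sample {self.sample_ids[idx[1]]!r}"
            )
        for sample in self.group_labels:
            if sample not in self.sample_ids:
                raise ValueError(f"group map names unknown sample {sample!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def groups(self) -> list[str]:
        """Distinct group names in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            g = self.group_labels.get(s)
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the samples labelled ``group``."""
        cols = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_labels.get(s) == group],
            dtype=int,
        )
        if cols.size == 0:
            raise KeyError(f"no samples labelled group {group!r}")
        return cols

    def group_values(self, group: str) -> np.ndarray:
        """Genes x group-samples submatrix."""
        return self.values[:, self.group_columns(group)]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"unknown gene IDs: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            group_labels=dict(self.group_labels),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class EssentialityTable:
    """Gene x cell-line p-value table from a pooled shRNA dropout screen.

    Each entry is the p-value attached to a per-gene, per-cell-line
    essentiality statistic (GARP-style). NaN marks a missing measurement.
    """

    gene_ids: list[str]
    cellline_ids: list[str]
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cellline_ids = [str(c) for c in self.cellline_ids]
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        _check_unique(self.gene_ids, "gene ID")
        if self.pvalues.shape != (len(self.gene_ids), len(self.cellline_ids)):
            raise ValueError("p-value matrix shape does not match gene/cell-line IDs")
        finite = self.pvalues[np.isfinite(self.pvalues)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            bad = np.argwhere(
                np.isfinite(self.pvalues) & ((self.pvalues < 0) | (self.pvalues > 1))
            )[0]
            raise ValueError(
                f"p-value outside [0, 1] at gene {self.gene_ids[bad[0]]!r}, "
                f"cell line {self.cellline_ids[bad[1]]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvalues, index=self.gene_ids, columns=self.cellline_ids)


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} {x!r}")
        seen.add(x)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def _to_numeric(df: pd.DataFrame, what: str, allow_missing: bool = False) -> np.ndarray:
    """Convert a string frame to float, naming the first offending cell."""
    raw = df.to_numpy(dtype=object)
    out = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip() == ""
            ):
                if allow_missing:
                    out[i, j] = np.nan
                    continue
                raise ValueError(
                    f"missing {what} value at row {df.index[i]!r}, column {df.columns[j]!r}"
                )
            try:
                out[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric {what} value {cell!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                ) from None
    return out


def read_expression_matrix(path, group_map=None) -> ExpressionMatrix:
    """Read an expression TSV (and optional group-map TSV) from disk.

    Row and column order are preserved from the file. Duplicate gene or
    sample IDs, non-numeric cells and missing values are hard errors —
    values are never imputed.
    """
    df = _read_tsv(path)
    values = _to_numeric(df, "expression")
    labels = read_group_map(group_map) if group_map is not None else {}
    return ExpressionMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        values=values,
        group_labels=labels,
    )


def read_group_map(path) -> dict[str, str]:
    """Read a two-column ``sample_id\tgroup`` TSV (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"group map must have exactly 2 columns, got {df.shape[1]}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_essentiality_table(path) -> EssentialityTable:
    """Read a gene x cell-line p-value TSV; empty cells become missing."""
    df = _read_tsv(path)
    pvals = _to_numeric(df, "p", allow_missing=True)
    return EssentialityTable(
        gene_ids=list(df.index.astype(str)),
        cellline_ids=list(df.columns.astype(str)),
        pvalues=pvals,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_group_map(group_labels: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(group_labels), "group": list(group_labels.values())}
    ).to_csv(path, sep="\t", index=False)


def write_essentiality_table(table: EssentialityTable, path) -> None:
    frame = table.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_edge_list(network, path) -> None:
    """Write a network as a ``source  target  weight`` TSV.

    Undirected coexpression networks write one row per edge; directed
    influence networks write one row per directed edge (two per node
    pair). Weights are written at full precision so a write-then-read
    round trip is lossless.
    """
    rows: list[tuple[str, str, float]]
    if hasattr(network, "directed_edges"):  # influence network
        rows = [(a, b, w) for (a, b), w in sorted(network.directed_edges.items())]
    elif hasattr(network, "edges"):
        rows = [(a, b, w) for (a, b), w in sorted(network.edges.items())]
    else:
        raise TypeError(f"cannot write edges of {type(network).__name__}")
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def _read_edges(path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(
        path, sep="\t", dtype={"source": str, "target": str, "weight": float},
        float_precision="round_trip",
    )
    for col in ("source", "target", "weight"):
        if col not in df.columns:
            raise ValueError(f"edge list is missing column {col!r}")
    return list(zip(df["source"], df["target"], df["weight"]))


def read_undirected_edge_list(path, alpha: float | None = None, n_samples: int | None = None):
    """Read an undirected edge-list TSV into a :class:`~influnet.coexpr.CoexpressionNetwork`."""
    from .coexpr import CoexpressionNetwork

    edges: dict[tuple[str, str], float] = {}
    nodes: dict[str, None] = {}
    for a, b, w in _read_edges(path):
        nodes.setdefault(a, None)
        nodes.setdefault(b, None)
        edges[tuple(sorted((a, b)))] = float(w)
    return CoexpressionNetwork(
        nodes=list(nodes), edges=edges, alpha=alpha, n_samples=n_samples
    )


def read_directed_edge_list(path):
    """Read a directed edge-list TSV into an :class:`~influnet.influence.InfluenceNetwork`."""
    from .influence import InfluenceNetwork

    directed: dict[tuple[str, str], float] = {}
    nodes: dict[str, None] = {}
    for a, b, w in _read_edges(path):
        nodes.setdefault(a, None)
        nodes.setdefault(b, None)
        directed[(a, b)] = float(w)
    return InfluenceNetwork(nodes=list(nodes), directed_edges=directed)
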