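"""End-to-end orchestration of the multi-condition influence analysis.

One configured run performs, per condition (sample group): differential
expression to fix the gene universe, coexpression network construction,
optional permutation validation of the edge count, influence network
conversion, influence scoring, centrality computation and (when an
essentiality table is supplied) essential-gene enrichment. A
cross-condition report then contrasts each condition's top influential
genes with the scores those same genes obtain under the other
conditions, with a random-gene-set control for the size of the change.

Outputs land in a directory tree (``networks/``, ``scores/``,
``reports/``) plus a JSON run manifest recording parameters, input
digests and per-stage gene/edge counts. Runs are deterministic given the
seed in the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .coexpr import build_coexpression_network, permutation_null
from .diffexpr import moderated_t_test, select_de_genes
from .expression_io import (
    ExpressionMatrix,
    read_essentiality_table,
    read_expression_matrix,
    write_edge_list,
)
from .influence import (
    InfluenceScoreTable,
    build_influence_network,
    cumulative_influence,
    select_influential,
)
from .netstats import centrality_table, enrichment_vs_background, essential_gene_set

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "CrossConditionReport",
    "PipelineError",
    "run_pipeline",
    "compare_across_conditions",
    "random_set_control",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    ``conditions`` lists the sample groups to build networks for;
    ``de_group_a`` / ``de_group_b`` define the differential-expression
    contrast whose significant genes become the shared gene universe
    (set both to ``None`` to skip DE filtering and use all genes).
    """

    expression: str
    groups: str
    output_dir: str
    essentiality: str | None = None
    conditions: list[str] = field(default_factory=list)
    de_group_a: str | None = None
    de_group_b: str | None = None
    fdr_threshold: float = 0.05
    alpha: float = 0.01
    n_permutations: int = 0
    selection_mode: str = "outlier"
    k: int = 25
    weight_mode: str = "reciprocal"
    t_test: str = "paired"
    n_random_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        if self.selection_mode not in ("outlier", "top_k"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.t_test not in ("paired", "unpaired"):
            raise ValueError(f"unknown t_test {self.t_test!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("expression", "groups", "essentiality"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} path does not exist: {value}")


@dataclass
class CrossConditionReport:
    """Top-set influence scores evaluated under every condition.

    ``score_matrices[c]`` holds condition ``c``'s top genes (rows) scored
    under each condition (columns); ``ttest_pvalues[(c, other)]`` is the
    p-value comparing the set's scores under ``c`` against its scores
    under ``other`` (NaN when the set is too small to test).
    """

    top_sets: dict
    score_matrices: dict
    ttest_pvalues: dict


def _scores_under(table: InfluenceScoreTable | None, genes: list[str]) -> np.ndarray:
    if table is None:
        return np.zeros(len(genes))
    return np.array([table.score_of(g, default=0.0) for g in genes])


def compare_across_conditions(
    tables: dict, top_sets: dict, test: str = "paired"
) -> CrossConditionReport:
    """Contrast each condition's top genes with their scores elsewhere.

    For each top set, a two-sample Student's t-test compares the set's
    in-condition scores against its scores under every other condition
    (paired by gene by default; ``test="unpaired"`` for independent
    samples). Genes absent from a condition's network score 0.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 conditions")
    if test not in ("paired", "unpaired"):
        raise ValueError(f"unknown test {test!r}")
    conditions = list(tables)
    matrices: dict = {}
    pvalues: dict = {}
    for cond, genes in top_sets.items():
        genes = list(genes)
        matrix = pd.DataFrame(
            {c: _scores_under(tables[c], genes) for c in conditions}, index=genes
        )
        matrices[cond] = matrix
        own = matrix[cond].to_numpy()
        for other in conditions:
            if other == cond:
                continue
            theirs = matrix[other].to_numpy()
            if len(genes) < 2:
                pvalues[(cond, other)] = float("nan")
                continue
            # degenerate cases the t machinery cannot express: identical
            # scores mean no difference (p = 1); a constant nonzero shift
            # is a sure difference (p -> 0)
            if test == "paired":
                degenerate = np.ptp(own - theirs) == 0
            else:
                degenerate = np.ptp(own) == 0 and np.ptp(theirs) == 0
            if degenerate:
                pvalues[(cond, other)] = 1.0 if np.allclose(own, theirs) else 0.0
                continue
            if test == "paired":
                result = stats.ttest_rel(own, theirs)
            else:
                result = stats.ttest_ind(own, theirs)
            pvalues[(cond, other)] = float(result.pvalue)
    return CrossConditionReport(
        top_sets={c: list(g) for c, g in top_sets.items()},
        score_matrices=matrices,
        ttest_pvalues=pvalues,
    )


def _change_statistic(tables: dict, cond: str, genes: list[str]) -> float:
    """Mean over the set of (own-condition score - mean other-condition score)."""
    others = [c for c in tables if c != cond]
    own = _scores_under(tables[cond], list(genes))
    other_mean = np.mean(
        [_scores_under(tables[c], list(genes)) for c in others], axis=0
    )
    return float(np.mean(own - other_mean))


def random_set_control(
    tables: dict, top_sets: dict, n_draws: int = 1000, seed: int = 0
) -> dict:
    """Empirical percentile of each top set's cross-condition score change.

    For each condition's top set, ``n_draws`` random gene sets of equal
    size are drawn from the union of all conditions' gene universes and
    the same change statistic is computed; the reported percentile uses
    the add-one rule (1 + #{draw <= observed}) / (1 + n_draws).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    universe = sorted({g for t in tables.values() for g in t.gene_ids})
    out: dict = {}
    rng = np.random.default_rng(seed)
    for cond, genes in top_sets.items():
        genes = list(genes)
        if len(genes) > len(universe):
            raise ValueError("top set larger than the gene universe")
        observed = _change_statistic(tables, cond, genes)
        draws = np.empty(n_draws)
        for d in range(n_draws):
            sample = list(rng.choice(universe, size=len(genes), replace=False))
            draws[d] = _change_statistic(tables, cond, sample)
        percentile = (1 + int(np.sum(draws <= observed))) / (1 + n_draws)
        out[cond] = {
            "observed_change": observed,
            "percentile": percentile,
            "n_draws": n_draws,
        }
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    class _StageContext:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                manifest["failed_stage"] = name
                manifest["partial"] = True
                raise PipelineError(name, exc) from exc
            return False

    return _StageContext()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and return the output directory.

    See the module docstring for the stage list. Determinism: all
    randomness (permutation null, random-set control) derives from
    ``config.seed``.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    (out / "scores").mkdir(exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "parameters": asdict(config),
        "input_digests": {
            name: _sha256(getattr(config, name))
            for name in ("expression", "groups", "essentiality")
            if getattr(config, name) is not None
        },
        "stages": {},
        "partial": False,
    }

    try:
        _run_stages(config, manifest, out)
    finally:
        # written even on stage failure so partial runs are flagged
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", out)
    return out


def _run_stages(config: RunConfig, manifest: dict, out: Path) -> None:
    with _stage(manifest, "load"):
        matrix = read_expression_matrix(config.expression, group_map=config.groups)
        essentiality = (
            read_essentiality_table(config.essentiality) if config.essentiality else None
        )
        conditions = config.conditions or matrix.groups()
        manifest["stages"]["load"] = {
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
            "conditions": conditions,
        }

    with _stage(manifest, "diffexpr"):
        if config.de_group_a and config.de_group_b:
            de = moderated_t_test(matrix, config.de_group_a, config.de_group_b)
            universe = select_de_genes(de, config.fdr_threshold)
            de.to_frame().to_csv(out / "reports" / "diffexpr.tsv", sep="\t", index=False)
            if len(universe) < 3:
                raise ValueError(
                    f"only {len(universe)} DE genes at FDR {config.fdr_threshold}; "
                    "need at least 3 to build a network"
                )
            matrix = matrix.subset_genes(universe)
            manifest["stages"]["diffexpr"] = {
                "contrast": [config.de_group_a, config.de_group_b],
                "n_de_genes": len(universe),
            }
        else:
            manifest["stages"]["diffexpr"] = {"skipped": True}

    tables: dict = {}
    top_sets: dict = {}
    for cond in conditions:
        with _stage(manifest, f"network:{cond}"):
            net = build_coexpression_network(matrix, cond, alpha=config.alpha)
            write_edge_list(net, out / "networks" / f"coexpr_{cond}.tsv")
            inet = build_influence_network(net)
            write_edge_list(inet, out / "networks" / f"influence_{cond}.tsv")
            table = cumulative_influence(inet)
            table.to_frame().to_csv(out / "scores" / f"influence_{cond}.tsv", sep="\t", index=False)
            ct = centrality_table(inet, config.weight_mode)
            ct.to_frame().to_csv(out / "scores" / f"centrality_{cond}.tsv", sep="\t", index=False)
            tables[cond] = table
            top_sets[cond] = select_influential(
                table,
                config.selection_mode,
                k=min(config.k, len(table.gene_ids)) if config.selection_mode == "top_k" else None,
            )
            stage_info = {
                "n_nodes": len(net.nodes),
                "n_edges": net.n_edges,
                "n_dropped_constant": len(net.dropped_genes),
                "n_selected": len(top_sets[cond]),
            }
            if config.n_permutations > 0:
                null = permutation_null(
                    matrix, cond, alpha=config.alpha,
                    n_replicates=config.n_permutations, seed=config.seed,
                )
                pd.DataFrame({"count": null.replicate_counts}).to_csv(
                    out / "reports" / f"null_{cond}.tsv", sep="\t", index=False
                )
                stage_info["permutation"] = {
                    "observed_count": null.observed_count,
                    "empirical_p": null.empirical_p,
                    "n_replicates": null.n_replicates,
                }
            else:
                stage_info["permutation"] = "skipped"
            manifest["stages"][f"network:{cond}"] = stage_info

    if essentiality is not None:
        with _stage(manifest, "enrichment"):
            essential = essential_gene_set(essentiality)
            rows = []
            for cond in conditions:
                selected = set(top_sets[cond])
                network_genes = set(tables[cond].gene_ids)
                if selected and len(network_genes - selected) > 0:
                    res = enrichment_vs_background(selected, network_genes, essential)
                    rows.append(
                        {
                            "condition": cond,
                            "set_size": res.set_size,
                            "essential_in_set": res.essential_in_set,
                            "background_size": res.background_size,
                            "essential_in_background": res.essential_in_background,
                            "binomial_p": res.binomial_p,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "reports" / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {"n_conditions": len(rows)}

    if len(conditions) >= 2:
        with _stage(manifest, "cross_condition"):
            testable = {c: s for c, s in top_sets.items() if len(s) >= 2}
            if testable:
                report = compare_across_conditions(tables, testable, test=config.t_test)
                rows = [
                    {"top_set_condition": c, "scored_under": o, "ttest_p": p}
                    for (c, o), p in report.ttest_pvalues.items()
                ]
                pd.DataFrame(rows).to_csv(
                    out / "reports" / "cross_condition.tsv", sep="\t", index=False
                )
                control = random_set_control(
                    tables, testable, n_draws=config.n_random_draws, seed=config.seed
                )
                pd.DataFrame(
                    [{"condition": c, **v} for c, v in control.items()]
                ).to_csv(out / "reports" / "random_set_control.tsv", sep="\t", index=False)
                manifest["stages"]["cross_condition"] = {
                    "ttest": {f"{c}|{o}": p for (c, o), p in report.ttest_pvalues.items()},
                    "random_set_control": control,
                }
            else:
                manifest["stages"]["cross_condition"] = {"skipped": "no testable top sets"}
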