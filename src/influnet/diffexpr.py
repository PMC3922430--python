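"""Differential expression with an empirical-Bayes moderated t-statistic.

Selects the gene universe that feeds coexpression analysis: a two-group
comparison (e.g. pre-treatment vs 90 days on drug) scored with a
moderated t-statistic. Per-gene pooled variances are shrunk toward a
common prior variance estimated by the method of moments on the log
sample variances — the classic microarray-era approach to stabilising
variance estimates when each gene has few replicates. The moderated
statistic is referred to a t distribution with augmented degrees of
freedom (residual df + estimated prior df), and p-values are corrected
with the Benjamini-Hochberg step-up rule.

This is a self-contained two-group analogue of the standard linear-model
moderated-t workflow; exact numerical equality with any particular
implementation of that workflow is not a contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .expression_io import ExpressionMatrix

__all__ = ["DEResult", "moderated_t_test", "bh_adjust", "select_de_genes"]


@dataclass
class DEResult:
    """Per-gene two-group differential-expression statistics.

    ``log_fold_change`` is mean(group_b) - mean(group_a) on the (log)
    scale of the input. ``prior_df`` / ``prior_var`` are the estimated
    empirical-Bayes hyperparameters (``prior_df`` may be ``inf`` when the
    sample variances show no excess spread over the prior).
    """

    gene_ids: list[str]
    log_fold_change: np.ndarray
    moderated_t: np.ndarray
    pvalue: np.ndarray
    fdr_adjusted_pvalue: np.ndarray
    prior_df: float
    prior_var: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "log_fold_change": self.log_fold_change,
                "moderated_t": self.moderated_t,
                "pvalue": self.pvalue,
                "fdr_adjusted_pvalue": self.fdr_adjusted_pvalue,
            }
        )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # trigamma(x) ~ 1/x for large x, ~ 1/x^2 for small x
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df, prior_var) to sample variances.

    Models s2 ~ prior_var * F(df, prior_df) via the log-variance
    representation: e = log(s2) - digamma(df/2) + log(df/2) has mean
    log(prior_var) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond trigamma(df/2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def moderated_t_test(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
) -> DEResult:
    """Two-group moderated t-test on every gene.

    Parameters
    ----------
    matrix:
        Expression matrix with both groups labelled.
    group_a, group_b:
        Group names; the reported fold change is ``mean(b) - mean(a)``.
    prior_df:
        ``None`` (default) estimates the prior degrees of freedom from
        the data; ``0`` disables shrinkage, reducing the statistic to the
        ordinary pooled-variance two-sample t.

    Genes with zero variance in both groups receive p = 1 with a warning.
    """
    xa = matrix.group_values(group_a)
    xb = matrix.group_values(group_b)
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least 2 samples")
    df_resid = float(na + nb - 2)
    lfc = xb.mean(axis=1) - xa.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / df_resid

    if prior_df is None:
        d0, s0 = _fit_variance_prior(s2, df_resid)
    else:
        if prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        d0 = float(prior_df)
        s0 = float(np.median(s2)) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    tstat = np.zeros_like(lfc)
    pval = np.ones_like(lfc)
    degenerate = se == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance in both groups; "
            "p-value set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
    live = ~degenerate
    tstat[live] = lfc[live] / se[live]
    if np.isinf(df_total):
        pval[live] = 2.0 * stats.norm.sf(np.abs(tstat[live]))
    else:
        pval[live] = 2.0 * stats.t.sf(np.abs(tstat[live]), df_total)
    return DEResult(
        gene_ids=list(matrix.gene_ids),
        log_fold_change=lfc,
        moderated_t=tstat,
        pvalue=pval,
        fdr_adjusted_pvalue=bh_adjust(pval),
        prior_df=d0,
        prior_var=s0,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def select_de_genes(result: DEResult, fdr_threshold: float = 0.05) -> list[str]:
    """Genes significant at the FDR threshold, ordered by (adjusted p, ID)."""
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must lie in (0, 1]")
    hits = [
        (adj, gid)
        for gid, adj in zip(result.gene_ids, result.fdr_adjusted_pvalue)
        if adj <= fdr_threshold
    ]
    hits.sort()
    return [gid for _, gid in hits]
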