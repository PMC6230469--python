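"""Preprocessing: grand-mean centering and gene filters.

The GP model assumes zero mean, so the single grand mean over all genes and
cells is subtracted from every entry.  Gene selection uses a one-way ANOVA
F-test across capture-time groups when capture times exist (genes whose
mean expression changes over capture times are most informative for the
ordering), and a joint high-mean/high-variance rule otherwise.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError
from .model import ExpressionMatrix

__all__ = ["center_data", "anova_gene_filter", "mean_variance_filter"]


def center_data(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract the overall mean across all genes and cells from each entry."""
    return ExpressionMatrix(
        expr.values - expr.values.mean(),
        gene_ids=list(expr.gene_ids),
        cell_ids=list(expr.cell_ids),
        capture_times=expr.capture_times,
    )


def anova_gene_filter(
    expr: ExpressionMatrix,
    n_keep: int = 100,
    p_threshold: Optional[float] = None,
) -> ExpressionMatrix:
    """Keep the genes most differential across capture times.

    Runs a per-gene one-way ANOVA F-test of equal mean expression across the
    capture-time groups and ranks genes by p-value.  Either the ``n_keep``
    smallest p-values are retained or, if ``p_threshold`` is given, all
    genes below it.
    """
    if expr.capture_times is None:
        raise InvalidInputError(
            "no capture times available; use mean_variance_filter instead"
        )
    groups = []
    for ct in np.unique(expr.capture_times):
        idx = np.flatnonzero(expr.capture_times == ct)
        if len(idx) < 2:
            raise InvalidInputError(
                f"capture time {ct!r} has fewer than 2 cells; ANOVA undefined"
            )
        groups.append(expr.values[:, idx])
    if len(groups) < 2:
        raise InvalidInputError(
            "need at least two capture times; use mean_variance_filter instead"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.f_oneway(*groups, axis=1)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    if p_threshold is not None:
        keep = np.flatnonzero(pvals < p_threshold)
        keep = keep[np.argsort(pvals[keep], kind="stable")]
    else:
        keep = np.argsort(pvals, kind="stable")[: min(n_keep, expr.n_genes)]
    return expr.subset_genes(np.sort(keep))


def mean_variance_filter(expr: ExpressionMatrix, n_keep: int) -> ExpressionMatrix:
    """Keep genes that are jointly high in mean expression and in variance.

    Genes are scored by the smaller of their (descending) mean rank and
    variance rank, i.e. a gene qualifies only if it sits high on *both*
    lists; the top ``n_keep`` scores are retained, ties broken by gene
    index.
    """
    means = expr.values.mean(axis=1)
    variances = expr.values.var(axis=1, ddof=1)
    # rank n_g = highest value, 1 = lowest
    mean_rank = stats.rankdata(means, method="ordinal")
    var_rank = stats.rankdata(variances, method="ordinal")
    score = np.minimum(mean_rank, var_rank)
    order = np.lexsort((np.arange(expr.n_genes), -score))
    keep = np.sort(order[: min(n_keep, expr.n_genes)])
    return expr.subset_genes(keep)
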