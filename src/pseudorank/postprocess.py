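"""Posterior summaries of sampled orderings.

The posterior over orderings is symmetric under full reversal (the GP
likelihood only sees pseudotime differences), so each order and its mirror
image are sampled with equal probability.  Before summarizing, sampled
orders whose cell positions correlate negatively with an anchor signal
(capture times, or a marker gene when no capture times exist) are replaced
by their reversal.  Summaries then report, per cell, the mean and standard
deviation of its geodesic pseudotime across draws and the frequency
distribution of its rank; draws can additionally be embedded in 2-D by
classical multidimensional scaling of their cell-position vectors, which
exposes multi-modal structure of the posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .exceptions import DegenerateDataError, InvalidInputError
from .model import ExpressionMatrix, rank_pseudotimes
from .sampler import ChainSamples

__all__ = [
    "PosteriorSummary",
    "resolve_reversals",
    "resolve_reversal_orders",
    "pool_orders",
    "summarize",
    "mds_positions",
    "gene_set_score",
]


@dataclass
class PosteriorSummary:
    """Per-cell pseudotime statistics and rank distribution."""

    cell_ids: List[str]
    mean_pseudotime: np.ndarray
    sd_pseudotime: np.ndarray
    position_freq: np.ndarray  # cells x ranks, rows sum to 1
    modal_order: np.ndarray  # cells sorted by mean pseudotime

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "mean_pseudotime": self.mean_pseudotime,
                "sd_pseudotime": self.sd_pseudotime,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def resolve_reversal_orders(orders: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Reverse every sampled order negatively correlated with ``anchor``.

    Correlation is Spearman's between each draw's cell-position vector and
    the anchor; since positions are already ranks, its sign is the sign of
    the covariance between positions and anchor ranks.  Zero correlation
    leaves the draw unchanged.
    """
    orders = np.asarray(orders)
    anchor = np.asarray(anchor)
    if anchor.ndim != 1 or anchor.shape[0] != orders.shape[1]:
        raise InvalidInputError("anchor must provide one value per cell")
    ranks = rankdata(anchor)
    if np.ptp(ranks) == 0:
        raise DegenerateDataError(
            "anchor is constant; reversal orientation undefined - use a "
            "marker-gene anchor instead"
        )
    centered = ranks - ranks.mean()
    positions = np.argsort(orders, axis=1)
    sign = positions @ centered
    out = orders.copy()
    flip = sign < 0
    out[flip] = out[flip, ::-1]
    return out


def resolve_reversals(samples: ChainSamples, anchor: np.ndarray) -> ChainSamples:
    """:func:`resolve_reversal_orders` applied to a chain's stored draws.

    Log-likelihood traces are unchanged: both pseudotime mappings only
    depend on pseudotime differences, which reversal preserves.
    """
    orders = resolve_reversal_orders(samples.orders, anchor)
    return ChainSamples(
        orders=orders,
        log_lik=samples.log_lik,
        log_sigma_w2=samples.log_sigma_w2,
        log_l=samples.log_l,
        iterations=samples.iterations,
        move_proposed=samples.move_proposed,
        move_accepted=samples.move_accepted,
        param_proposed=samples.param_proposed,
        param_accepted=samples.param_accepted,
        param_proposed_post=samples.param_proposed_post,
        param_accepted_post=samples.param_accepted_post,
        meta=dict(samples.meta, reversal_resolved=True),
    )


def pool_orders(
    chains: Sequence[ChainSamples], discard_frac: float = 0.5
) -> np.ndarray:
    """Pool post-burn-in order draws across chains."""
    pooled = []
    for c in chains:
        lo = int(c.n_stored * discard_frac)
        pooled.append(c.orders[lo:])
    return np.concatenate(pooled, axis=0)


def _draw_pseudotimes(
    orders: np.ndarray, expr: ExpressionMatrix, mode: str
) -> np.ndarray:
    """Pseudotime of every cell in every draw, cells in column order of ``expr``."""
    n, T = orders.shape
    if mode == "geodesic":
        d = expr.cell_distances()
        steps = d[orders[:, :-1], orders[:, 1:]]
        tau_pos = np.concatenate(
            (np.zeros((n, 1)), np.cumsum(steps, axis=1)), axis=1
        )
        totals = tau_pos[:, -1]
        if np.any(totals <= 0):
            raise DegenerateDataError("a draw has all-identical consecutive cells")
        tau_pos /= totals[:, None]
    elif mode == "rank":
        tau_pos = np.broadcast_to(rank_pseudotimes(T), (n, T))
    else:
        raise InvalidInputError(f"unknown pseudotime mode {mode!r}")
    positions = np.argsort(orders, axis=1)
    return np.take_along_axis(np.ascontiguousarray(tau_pos), positions, axis=1)


def summarize(
    orders_or_chains: Union[np.ndarray, Sequence[ChainSamples]],
    expr: ExpressionMatrix,
    mode: str = "geodesic",
    discard_frac: float = 0.5,
) -> PosteriorSummary:
    """Posterior pseudotime summary from (pooled, reversal-resolved) draws.

    For every draw the geodesic pseudotimes are recomputed; per cell the
    mean and standard deviation over draws are reported together with the
    row-stochastic cell-by-rank frequency matrix.  The modal ordering sorts
    cells by mean pseudotime (ties broken by cell index).
    """
    if isinstance(orders_or_chains, np.ndarray):
        orders = orders_or_chains
        if orders.ndim == 1:
            orders = orders[None, :]
    else:
        orders = pool_orders(orders_or_chains, discard_frac=discard_frac)
    if orders.shape[0] < 1:
        raise InvalidInputError("need at least one stored draw")
    n, T = orders.shape
    tau_cell = _draw_pseudotimes(orders, expr, mode)
    mean_pt = tau_cell.mean(axis=0)
    sd_pt = tau_cell.std(axis=0)
    freq = np.zeros((T, T))
    cols = np.broadcast_to(np.arange(T), (n, T))
    np.add.at(freq, (orders.ravel(), cols.ravel()), 1.0)
    freq /= n
    modal = np.argsort(mean_pt, kind="stable")
    return PosteriorSummary(
        cell_ids=list(expr.cell_ids),
        mean_pseudotime=mean_pt,
        sd_pseudotime=sd_pt,
        position_freq=freq,
        modal_order=modal,
    )


def mds_positions(
    orders: np.ndarray, n_draws_used: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Classical MDS embedding of the draws' cell-position vectors.

    Double-centers the squared Euclidean distance matrix between position
    vectors and eigendecomposes it; returns the first two coordinates (or
    one, with a warning, if fewer than two positive eigenvalues exist) and
    the eigenvalues in decreasing order.
    """
    orders = np.asarray(orders)
    if orders.ndim != 2 or orders.shape[0] < 3:
        raise InvalidInputError("need at least three draws for an MDS embedding")
    if n_draws_used is not None and n_draws_used < orders.shape[0]:
        idx = np.linspace(0, orders.shape[0] - 1, n_draws_used).astype(int)
        orders = orders[idx]
    positions = np.argsort(orders, axis=1).astype(float)
    d2 = squareform(pdist(positions, metric="sqeuclidean"))
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    idx = np.argsort(vals)[::-1]
    vals, vecs = vals[idx], vecs[:, idx]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(vals[0]), 1.0)
    n_pos = int(np.sum(vals > tol))
    if n_pos < 2:
        warnings.warn(
            "position vectors span fewer than two dimensions; returning a "
            "1-D embedding",
            RuntimeWarning,
            stacklevel=2,
        )
        k = max(n_pos, 1)
    else:
        k = 2
    coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    return coords, vals


def gene_set_score(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    summary: PosteriorSummary,
) -> pd.DataFrame:
    """Per-cell mean expression of a gene set against mean pseudotime.

    The classic use is a response signature (e.g. a core antiviral module):
    plotting the score over mean pseudotime checks that the inferred
    ordering tracks the biological process.
    """
    gene_set = list(dict.fromkeys(map(str, gene_set)))
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise InvalidInputError(f"genes not found in the data: {missing}")
    rows = [index[g] for g in gene_set]
    score = expr.values[rows].mean(axis=0)
    return pd.DataFrame(
        {
            "cell_id": expr.cell_ids,
            "mean_pseudotime": summary.mean_pseudotime,
            "score": score,
        }
    ).sort_values("mean_pseudotime", ignore_index=True)
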