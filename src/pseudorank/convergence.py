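"""Gelman-Rubin convergence assessment on scalar summaries of the chains.

Two scalar summaries are monitored: the log-likelihood trace and the L1
distance of each sampled permutation's cell-position vector from a fixed
reference permutation (the true order when known, else the identity).  The
potential scale reduction factor is the variant corrected for sampling
variability,

    R = sqrt( (d + 3) / (d + 1) * V / W ),

where ``W`` is the mean within-chain variance, ``V = (n-1)/n W +
(1 + 1/m) B/n`` the pooled posterior-variance estimate from ``m`` chains of
length ``n`` with between-chain variance ``B``, and ``d = 2 V^2 / var(V)``
the estimated degrees of freedom of ``V``.  ``var(V)`` combines the
variances of the chain means and variances and their covariance exactly as
in the standard corrected-PSRF formulation, so an independent transcription
of that formula can serve as an oracle in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .sampler import ChainSamples

__all__ = [
    "ConvergenceReport",
    "l1_position_distance",
    "l1_position_distances",
    "gelman_rubin",
    "assess",
]


def l1_position_distance(order: np.ndarray, reference: np.ndarray) -> int:
    """Sum over cells of the absolute difference of their positions in two
    permutations."""
    return int(l1_position_distances(np.asarray(order)[None, :], reference)[0])


def l1_position_distances(orders: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorized :func:`l1_position_distance` over rows of ``orders``."""
    orders = np.asarray(orders)
    reference = np.asarray(reference)
    T = reference.shape[0]
    if orders.ndim != 2 or orders.shape[1] != T:
        raise InvalidInputError("orders and reference must have the same length")
    for perm in (orders[0], reference):
        if not np.array_equal(np.sort(perm), np.arange(T)):
            raise InvalidInputError("inputs must be permutations of 0..T-1")
    positions = np.argsort(orders, axis=1)
    ref_positions = np.argsort(reference)
    return np.abs(positions - ref_positions[None, :]).sum(axis=1)


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Corrected potential scale reduction factor of scalar traces.

    Returns ``nan`` (with a warning) when every chain has zero within-chain
    variance, since a frozen chain carries no evidence of convergence.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise InvalidInputError("need >= 2 chains of equal length >= 4")
    m, n = x.shape
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    W = float(chain_vars.mean())
    B = n * float(chain_means.var(ddof=1))
    if W == 0.0:
        warnings.warn(
            "all chains have zero within-chain variance; R-hat undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    V = (n - 1) / n * W + (1.0 + 1.0 / m) * B / n
    # Sampling-variability correction: estimate var(V) from the empirical
    # (co)variances of the per-chain means and variances.
    mu = float(chain_means.mean())
    var_w = float(chain_vars.var(ddof=1)) / m
    var_b = 2.0 * B**2 / (m - 1)
    cov_s2_xbar2 = float(np.cov(chain_vars, chain_means**2, ddof=1)[0, 1])
    cov_s2_xbar = float(np.cov(chain_vars, chain_means, ddof=1)[0, 1])
    cov_wb = (n / m) * (cov_s2_xbar2 - 2.0 * mu * cov_s2_xbar)
    var_v = (
        ((n - 1) ** 2) * var_w
        + ((1.0 + 1.0 / m) ** 2) * var_b
        + 2.0 * (n - 1) * (1.0 + 1.0 / m) * cov_wb
    ) / n**2
    if var_v <= 0:
        correction = 1.0
    else:
        d = 2.0 * V**2 / var_v
        correction = (d + 3.0) / (d + 1.0)
    return float(np.sqrt(correction * V / W))


@dataclass
class ConvergenceReport:
    """R-hat curves over increasing sample counts plus the final verdict."""

    sample_counts: np.ndarray
    rhat_loglik: np.ndarray
    rhat_l1: np.ndarray
    threshold: float
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_count": self.sample_counts,
                "rhat_loglik": self.rhat_loglik,
                "rhat_l1": self.rhat_l1,
                "converged": (
                    np.isfinite(self.rhat_loglik)
                    & np.isfinite(self.rhat_l1)
                    & (self.rhat_loglik < self.threshold)
                    & (self.rhat_l1 < self.threshold)
                ),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def assess(
    chains: List[ChainSamples],
    reference: Optional[np.ndarray] = None,
    threshold: float = 1.1,
    anchor: Optional[np.ndarray] = None,
    n_points: int = 10,
) -> ConvergenceReport:
    """Gelman-Rubin assessment of a set of chains.

    At each of ``n_points`` logarithmically spaced sample counts the first
    half of the available thinned samples is discarded and the corrected
    PSRF computed for the log-likelihood and for the L1 position distance to
    ``reference`` (identity permutation by default).  When ``anchor``
    (per-cell capture times or a marker signal) is given, sampled orders
    negatively correlated with it are reversed first, folding the two
    orientations of the reversal-symmetric posterior onto one before
    distances are measured.
    """
    if len(chains) < 2:
        raise InvalidInputError("need at least two chains")
    n = min(c.n_stored for c in chains)
    T = chains[0].n_cells
    if reference is None:
        reference = np.arange(T)
    orders = [c.orders[:n] for c in chains]
    if anchor is not None:
        from .postprocess import resolve_reversal_orders

        orders = [resolve_reversal_orders(o, anchor) for o in orders]
    loglik = np.stack([c.log_lik[:n] for c in chains])
    l1 = np.stack([l1_position_distances(o, reference) for o in orders]).astype(float)
    if n < 8:
        raise InvalidInputError("need at least 8 thinned samples per chain")
    counts = np.unique(np.geomspace(max(8, n // 64), n, num=n_points).astype(int))
    counts = counts[(counts >= 8) & (counts <= n)]
    rh_ll = np.empty(len(counts))
    rh_l1 = np.empty(len(counts))
    for k, cnt in enumerate(counts):
        lo = cnt // 2
        rh_ll[k] = gelman_rubin(loglik[:, lo:cnt])
        rh_l1[k] = gelman_rubin(l1[:, lo:cnt])
    converged = bool(
        np.isfinite(rh_ll[-1])
        and np.isfinite(rh_l1[-1])
        and rh_ll[-1] < threshold
        and rh_l1[-1] < threshold
    )
    return ConvergenceReport(
        sample_counts=counts,
        rhat_loglik=rh_ll,
        rhat_l1=rh_l1,
        threshold=threshold,
        converged=converged,
    )
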