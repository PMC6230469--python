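"""Proposal moves on permutations for the Metropolis-Hastings order sampler.

Five kernels are mixed: (1) iterated swaps of neighbouring cells, (2) swaps
of two cells with a short L1 distance in expression space, (3) reversal of
the segment between two such cells, (4) uniformly random permutations of
short segments, and (5) reversal of the whole ordering.  Moves 2 and 3 pick
an unordered position pair (i, j) with probability proportional to
``exp(-d(c_i, c_j)^2 / gamma)`` where ``d`` is the L1 distance of the cells
currently at those positions; long-range exchanges therefore only happen
between cells with similar profiles, keeping the trajectory smooth.

Every kernel is symmetric, so the Metropolis acceptance ratio reduces to the
posterior ratio.  For moves 2/3 symmetry holds because the pair-weight
normaliser sums over all unordered cell pairs (order-invariant) and the
selected pair's weight is preserved by the move; the test suite verifies
this by exhaustive enumeration rather than taking it on faith.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import ConfigurationError, InvalidInputError
from .model import ExpressionMatrix

__all__ = [
    "MoveConfig",
    "PairDistanceTable",
    "move1_neighbor_swaps",
    "move2_distance_swap",
    "move3_distance_reversal",
    "move4_short_permutations",
    "move5_full_reversal",
    "propose_order",
]


@dataclass
class MoveConfig:
    """Move mixture probabilities and tuning constants.

    Defaults follow the recommended settings: ``n0 = floor(T/4)`` neighbour
    swaps at most, ``n3 = floor(T/20)`` short permutations of length up to
    ``n3a = floor(T/12)``, full reversal with probability 0.002 and the
    remaining mass split equally over moves 1-4.  ``gamma`` scales the pair
    weights of moves 2/3; when ``None`` it is set from the data (median of
    squared pairwise L1 distances), making the weights scale-free.  ``alpha``
    tempers the move-2/3 pair distributions (weights raised to ``alpha``) to
    lower their acceptance rates if required; default 1 (no tempering).
    """

    probabilities: Tuple[float, float, float, float, float]
    n0: int
    n3: int
    n3a: int
    gamma: Optional[float] = None
    alpha: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (5,) or np.any(p < 0):
            raise ConfigurationError("need 5 nonnegative move probabilities")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ConfigurationError(f"move probabilities sum to {p.sum()!r}, not 1")
        self.probabilities = tuple(float(x) for x in p)
        if self.n0 < 1 or self.n3 < 1 or self.n3a < 3:
            raise ConfigurationError("require n0 >= 1, n3 >= 1, n3a >= 3")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")

    @classmethod
    def defaults(
        cls,
        n_cells: int,
        p5: float = 0.002,
        gamma: Optional[float] = None,
        alpha: float = 1.0,
        active_moves: Tuple[int, ...] = (1, 2, 3, 4),
    ) -> "MoveConfig":
        """Default configuration for ``T`` cells.

        ``active_moves`` selects which of moves 1-4 share the probability
        mass ``1 - p5`` equally (move 5 keeps probability ``p5``); single-move
        runs e.g. use ``active_moves=(3,)``.
        """
        if not active_moves or any(m not in (1, 2, 3, 4) for m in active_moves):
            raise ConfigurationError("active_moves must be a nonempty subset of 1..4")
        p = [0.0] * 5
        share = (1.0 - p5) / len(active_moves)
        for m in active_moves:
            p[m - 1] = share
        p[4] = p5
        return cls(
            probabilities=tuple(p),
            n0=max(n_cells // 4, 1),
            n3=max(n_cells // 20, 1),
            n3a=max(n_cells // 12, 3),
            gamma=gamma,
            alpha=alpha,
        )


class PairDistanceTable:
    """Pairwise L1 distances between cells and the derived pair weights.

    Weights ``w(a, b) = exp(-d(a, b)^2 / gamma)^alpha`` are indexed by cell
    identity and cached once; sampling a position pair under the current
    ordering is equivalent to sampling a cell pair from this fixed
    categorical distribution and looking up the cells' positions, because
    the position-pair weight equals the weight of the cells occupying those
    positions.
    """

    def __init__(
        self, l1_distances: np.ndarray, gamma: Optional[float] = None, alpha: float = 1.0
    ) -> None:
        d = np.asarray(l1_distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise InvalidInputError("l1_distances must be a square matrix")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise InvalidInputError("l1_distances must be symmetric with zero diagonal")
        n = d.shape[0]
        iu = np.triu_indices(n, k=1)
        sq = d[iu] ** 2
        if gamma is None:
            med = float(np.median(sq))
            gamma = med if med > 0 else 1.0
        self.n_cells = n
        self.gamma = float(gamma)
        self.alpha = float(alpha)
        self.distances = d
        w = np.exp(-alpha * sq / self.gamma)
        self._pairs_a, self._pairs_b = iu
        self.normalizer = float(w.sum())
        self._cum = np.cumsum(w / self.normalizer)
        self.weights = np.zeros_like(d)
        self.weights[iu] = w
        self.weights += self.weights.T

    @classmethod
    def from_expression(
        cls, expr: ExpressionMatrix, gamma: Optional[float] = None, alpha: float = 1.0
    ) -> "PairDistanceTable":
        d = pdist(expr.values.T, metric="cityblock")
        from scipy.spatial.distance import squareform

        return cls(squareform(d), gamma=gamma, alpha=alpha)

    def sample_cell_pair(self, rng: np.random.Generator) -> Tuple[int, int]:
        """Draw an unordered cell pair with probability proportional to its weight."""
        k = int(np.searchsorted(self._cum, rng.random(), side="right"))
        k = min(k, len(self._pairs_a) - 1)
        return int(self._pairs_a[k]), int(self._pairs_b[k])

    def pair_probability(self, a: int, b: int) -> float:
        """Exact selection probability of the unordered cell pair (a, b)."""
        if a == b:
            raise InvalidInputError("a pair consists of two distinct cells")
        return float(self.weights[a, b] / self.normalizer)


def move1_neighbor_swaps(
    o: np.ndarray, cfg: MoveConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply r1 ~ U{1..n0} adjacent transpositions at uniform positions."""
    T = len(o)
    if T < 2:
        raise InvalidInputError("need at least two cells")
    out = o.copy()
    r1 = int(rng.integers(1, cfg.n0 + 1))
    positions = rng.integers(0, T - 1, size=r1)
    for p in positions:
        out[p], out[p + 1] = out[p + 1], out[p]
    return out


def move2_distance_swap(
    o: np.ndarray, table: PairDistanceTable, rng: np.random.Generator
) -> np.ndarray:
    """Swap the two cells of a weight-sampled pair."""
    a, b = table.sample_cell_pair(rng)
    out = o.copy()
    i = int(np.flatnonzero(out == a)[0])
    j = int(np.flatnonzero(out == b)[0])
    out[i], out[j] = out[j], out[i]
    return out


def move3_distance_reversal(
    o: np.ndarray, table: PairDistanceTable, rng: np.random.Generator
) -> np.ndarray:
    """Reverse the segment between (and including) a weight-sampled cell pair."""
    a, b = table.sample_cell_pair(rng)
    out = o.copy()
    i = int(np.flatnonzero(out == a)[0])
    j = int(np.flatnonzero(out == b)[0])
    if i > j:
        i, j = j, i
    out[i : j + 1] = out[i : j + 1][::-1]
    return out


def move4_short_permutations(
    o: np.ndarray, cfg: MoveConfig, rng: np.random.Generator
) -> np.ndarray:
    """Randomly permute r2 ~ U{1..n3} short segments of length 3..max(n3a, 3)."""
    T = len(o)
    if T < 4:
        raise InvalidInputError("move 4 requires at least 4 cells")
    out = o.copy()
    r2 = int(rng.integers(1, cfg.n3 + 1))
    max_len = min(max(cfg.n3a, 3), T - 1)
    for _ in range(r2):
        seg = int(rng.integers(3, max_len + 1))
        k = int(rng.integers(0, T - seg))
        out[k : k + seg] = out[k : k + seg][rng.permutation(seg)]
    return out


def move5_full_reversal(o: np.ndarray) -> np.ndarray:
    """Reverse the entire ordering."""
    return o[::-1].copy()


def propose_order(
    o: np.ndarray,
    cfg: MoveConfig,
    table: Optional[PairDistanceTable],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, int]:
    """Select a move by its probability and apply it.

    Returns the proposed permutation and the 1-based id of the move that
    fired.  ``table`` may be ``None`` only if moves 2 and 3 have zero
    probability.
    """
    u = rng.random()
    p = cfg.probabilities
    acc = 0.0
    move = 5
    for m in range(5):
        acc += p[m]
        if u < acc:
            move = m + 1
            break
    if move in (2, 3) and table is None:
        raise ConfigurationError("moves 2/3 need a PairDistanceTable")
    if move == 1:
        return move1_neighbor_swaps(o, cfg, rng), 1
    if move == 2:
        return move2_distance_swap(o, table, rng), 2
    if move == 3:
        return move3_distance_reversal(o, table, rng), 3
    if move == 4:
        return move4_short_permutations(o, cfg, rng), 4
    return move5_full_reversal(o), 5
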