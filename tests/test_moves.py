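import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pseudorank import ConfigurationError, MoveConfig, PairDistanceTable, propose_order
from pseudorank.moves import (
    move1_neighbor_swaps,
    move2_distance_swap,
    move3_distance_reversal,
    move4_short_permutations,
    move5_full_reversal,
)

from conftest import ScriptedRNG, make_expr


def equal_distance_table(n):
    d = np.ones((n, n)) - np.eye(n)
    return PairDistanceTable(d, gamma=1.0)


def perm_index(T):
    perms = list(itertools.permutations(range(T)))
    return perms, {p: i for i, p in enumerate(perms)}


class TestMoveConfig:
    def test_defaults_match_cell_count(self):
        cfg = MoveConfig.defaults(90)
        assert (cfg.n0, cfg.n3, cfg.n3a) == (22, 4, 7)
        assert cfg.probabilities[4] == 0.002
        assert np.allclose(cfg.probabilities[:4], (1 - 0.002) / 4)
        assert sum(cfg.probabilities) == pytest.approx(1.0, abs=1e-15)

    def test_small_t_floors(self):
        cfg = MoveConfig.defaults(5)
        assert (cfg.n0, cfg.n3, cfg.n3a) == (1, 1, 3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"probabilities": (0.5, 0.5, 0.0, 0.0, 0.1), "n0": 1, "n3": 1, "n3a": 3},
            {"probabilities": (1.0, 0, 0, 0, 0), "n0": 0, "n3": 1, "n3a": 3},
            {"probabilities": (1.0, 0, 0, 0, 0), "n0": 1, "n3": 1, "n3a": 2},
            {"probabilities": (1.0, 0, 0, 0, 0), "n0": 1, "n3": 1, "n3a": 3,
             "alpha": 0.0},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ConfigurationError):
            MoveConfig(**kwargs)


class TestMoveExamples:
    def test_single_neighbor_swap(self):
        cfg = MoveConfig.defaults(4)
        rng = ScriptedRNG(integers=[1, 1])
        out = move1_neighbor_swaps(np.array([0, 1, 2, 3]), cfg, rng)
        assert list(out) == [0, 2, 1, 3]

    def test_double_swap_is_identity(self):
        cfg = MoveConfig((1, 0, 0, 0, 0), n0=2, n3=1, n3a=3)
        rng = ScriptedRNG(integers=[2, 0, 0])
        out = move1_neighbor_swaps(np.array([0, 1]), cfg, rng)
        assert list(out) == [0, 1]

    def test_distance_swap_exchanges_selected_cells(self):
        table = equal_distance_table(5)
        # pair index 5 in upper-triangular order is (1, 3)
        rng = ScriptedRNG(randoms=[0.55])
        out = move2_distance_swap(np.arange(5), table, rng)
        assert list(out) == [0, 3, 2, 1, 4]

    def test_segment_reversal_between_selected_cells(self):
        table = equal_distance_table(5)
        rng = ScriptedRNG(randoms=[0.55])  # cells 1 and 3 at positions 1 and 3
        out = move3_distance_reversal(np.arange(5), table, rng)
        assert list(out) == [0, 3, 2, 1, 4]

    def test_short_permutation_is_local(self):
        cfg = MoveConfig((0, 0, 0, 1, 0), n0=1, n3=1, n3a=3)
        rng = ScriptedRNG(integers=[1, 3, 0], permutations=[[2, 1, 0]])
        out = move4_short_permutations(np.array([0, 1, 2, 3]), cfg, rng)
        assert list(out) == [2, 1, 0, 3]
        rng = ScriptedRNG(integers=[1, 3, 0], permutations=[[0, 1, 2]])
        out = move4_short_permutations(np.array([0, 1, 2, 3]), cfg, rng)
        assert list(out) == [0, 1, 2, 3]

    def test_full_reversal_involution(self):
        o = np.array([0, 1, 2])
        assert list(move5_full_reversal(o)) == [2, 1, 0]
        assert list(move5_full_reversal(move5_full_reversal(o))) == list(o)


def exact_kernel_move1(cfg, T):
    """Enumerate all swap sequences of move 1."""
    perms, index = perm_index(T)
    q = np.zeros((len(perms), len(perms)))
    for start in perms:
        i = index[start]
        for r1 in range(1, cfg.n0 + 1):
            p_seq = 1.0 / cfg.n0 / (T - 1) ** r1
            for seq in itertools.product(range(T - 1), repeat=r1):
                o = list(start)
                for p in seq:
                    o[p], o[p + 1] = o[p + 1], o[p]
                q[i, index[tuple(o)]] += p_seq
    return q


def exact_kernel_pairs(table, T, reversal):
    """Enumerate the pair-weighted swap (move 2) or reversal (move 3) kernel."""
    perms, index = perm_index(T)
    q = np.zeros((len(perms), len(perms)))
    for start in perms:
        i = index[start]
        for a in range(T):
            for b in range(a + 1, T):
                prob = table.pair_probability(a, b)
                o = list(start)
                ia, ib = o.index(a), o.index(b)
                lo, hi = min(ia, ib), max(ia, ib)
                if reversal:
                    o[lo : hi + 1] = o[lo : hi + 1][::-1]
                else:
                    o[lo], o[hi] = o[hi], o[lo]
                q[i, index[tuple(o)]] += prob
    return q


def exact_kernel_move4(cfg, T):
    perms, index = perm_index(T)
    q = np.zeros((len(perms), len(perms)))
    assert cfg.n3 == 1
    seg = 3
    n_starts = T - seg
    for start in perms:
        i = index[start]
        for k in range(n_starts):
            for sub in itertools.permutations(range(seg)):
                o = list(start)
                o[k : k + seg] = [o[k + j] for j in sub]
                q[i, index[tuple(o)]] += 1.0 / (n_starts * 6)
    return q


class TestKernelSymmetry:
    """Every proposal kernel must satisfy q(a->b) = q(b->a) exactly, so the
    Metropolis ratio can omit the proposal term."""

    def test_move1_enumerated(self):
        cfg = MoveConfig((1, 0, 0, 0, 0), n0=2, n3=1, n3a=3)
        q = exact_kernel_move1(cfg, 4)
        assert np.allclose(q.sum(axis=1), 1.0)
        assert np.allclose(q, q.T, atol=1e-14)

    @pytest.mark.parametrize("reversal", [False, True])
    def test_moves_2_3_enumerated(self, rng, reversal):
        expr = make_expr(rng, n_genes=4, n_cells=4)
        table = PairDistanceTable.from_expression(expr)
        q = exact_kernel_pairs(table, 4, reversal)
        assert np.allclose(q.sum(axis=1), 1.0)
        assert np.allclose(q, q.T, atol=1e-14)

    def test_move4_enumerated(self):
        cfg = MoveConfig((0, 0, 0, 1, 0), n0=1, n3=1, n3a=3)
        q = exact_kernel_move4(cfg, 5)
        assert np.allclose(q.sum(axis=1), 1.0)
        assert np.allclose(q, q.T, atol=1e-14)


class TestPairSelection:
    def test_equal_distances_select_uniformly(self, rng):
        table = equal_distance_table(5)
        n = 20_000
        counts = np.zeros(10)
        pair_to_idx = {
            p: i for i, p in enumerate(itertools.combinations(range(5), 2))
        }
        for _ in range(n):
            counts[pair_to_idx[table.sample_cell_pair(rng)]] += 1
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_large_gamma_is_uniform(self, rng):
        expr = make_expr(rng, n_genes=3, n_cells=6)
        table = PairDistanceTable.from_expression(expr, gamma=1e12)
        probs = [
            table.pair_probability(a, b)
            for a, b in itertools.combinations(range(6), 2)
        ]
        assert np.allclose(probs, 1.0 / 15, rtol=1e-6)

    def test_normalizer_sums_all_pairs(self, rng):
        expr = make_expr(rng, n_genes=3, n_cells=6)
        table = PairDistanceTable.from_expression(expr)
        total = sum(
            table.pair_probability(a, b)
            for a, b in itertools.combinations(range(6), 2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_tempering_flattens_weights(self, rng):
        expr = make_expr(rng, n_genes=3, n_cells=6)
        sharp = PairDistanceTable.from_expression(expr, alpha=1.0)
        flat = PairDistanceTable.from_expression(expr, alpha=0.1)
        ratio = lambda t: max(
            t.pair_probability(a, b)
            for a, b in itertools.combinations(range(6), 2)
        ) / min(
            t.pair_probability(a, b)
            for a, b in itertools.combinations(range(6), 2)
        )
        assert ratio(flat) < ratio(sharp)


class TestProposeOrder:
    def test_forced_full_reversal(self, rng):
        cfg = MoveConfig((0, 0, 0, 0, 1.0), n0=1, n3=1, n3a=3)
        out, move_id = propose_order(np.arange(5), cfg, None, rng)
        assert move_id == 5
        assert list(out) == [4, 3, 2, 1, 0]

    def test_move_frequencies_match_probabilities(self, rng):
        expr = make_expr(rng, n_genes=3, n_cells=8)
        table = PairDistanceTable.from_expression(expr)
        cfg = MoveConfig((0.4, 0.3, 0.2, 0.08, 0.02), n0=2, n3=1, n3a=3)
        n = 20_000
        counts = np.zeros(5)
        o = np.arange(8)
        for _ in range(n):
            _, mid = propose_order(o, cfg, table, rng)
            counts[mid - 1] += 1
        assert stats.chisquare(
            counts, np.array(cfg.probabilities) * n
        ).pvalue > 1e-3

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=4, max_value=9),
        st.integers(min_value=0, max_value=10_000),
    )
    def test_output_always_a_permutation(self, T, seed):
        r = np.random.default_rng(seed)
        expr = make_expr(r, n_genes=2, n_cells=T)
        table = PairDistanceTable.from_expression(expr)
        cfg = MoveConfig.defaults(T, p5=0.1)
        o = r.permutation(T)
        for _ in range(10):
            o, _ = propose_order(o, cfg, table, r)
            assert np.array_equal(np.sort(o), np.arange(T))


class TestIrreducibility:
    def test_moves_1_to_4_reach_all_permutations(self, rng):
        """Union of the exact supports of moves 1-4 connects all of S_4."""
        expr = make_expr(rng, n_genes=3, n_cells=4)
        table = PairDistanceTable.from_expression(expr)
        cfg = MoveConfig((0.25, 0.25, 0.25, 0.25, 0.0), n0=1, n3=1, n3a=3)
        q = (
            exact_kernel_move1(cfg, 4)
            + exact_kernel_pairs(table, 4, False)
            + exact_kernel_pairs(table, 4, True)
            + exact_kernel_move4(cfg, 4)
        )
        reach = {0}
        frontier = [0]
        while frontier:
            s = frontier.pop()
            for t in np.flatnonzero(q[s] > 0):
                if t not in reach:
                    reach.add(int(t))
                    frontier.append(int(t))
        assert len(reach) == 24
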