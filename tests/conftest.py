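import numpy as np
import pytest

from pseudorank import ExpressionMatrix, GPHyperParams


class ScriptedRNG:
    """Stand-in for a numpy Generator that replays scripted draws.

    Lets tests pin down the exact stochastic choices of a proposal move
    (number of swaps, positions, segment permutations) so the documented
    examples can be asserted deterministically.
    """

    def __init__(self, integers=(), randoms=(), permutations=()):
        self._integers = list(integers)
        self._randoms = list(randoms)
        self._permutations = list(permutations)

    def integers(self, low, high=None, size=None):
        if size is None:
            return self._integers.pop(0)
        return np.array([self._integers.pop(0) for _ in range(int(size))])

    def random(self):
        return self._randoms.pop(0)

    def permutation(self, n):
        return np.asarray(self._permutations.pop(0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_expr(rng, n_genes=3, n_cells=6, capture_blocks=None, scale=1.0):
    values = scale * rng.normal(size=(n_genes, n_cells))
    capture = None
    if capture_blocks is not None:
        assert sum(capture_blocks) == n_cells
        capture = np.repeat(np.arange(len(capture_blocks)), capture_blocks)
    return ExpressionMatrix(
        values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        capture_times=capture,
    )


@pytest.fixture
def small_expr(rng):
    return make_expr(rng, n_genes=3, n_cells=6)


@pytest.fixture
def default_params():
    return GPHyperParams(1.0, 0.5, 0.4)
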