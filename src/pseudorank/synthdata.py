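"""Synthetic GP-trajectory datasets for the simulation studies and tests.

Each dataset draws ``T`` latent input times uniformly on [0, 1] and, per
gene, a hyperparameter triple ``(sigma_w, l, sigma_eps)`` from log-normal
laws; the gene's trajectory is then a draw from the noise-free squared
exponential GP at those input times plus iid ``N(0, sigma_eps^2)`` noise
(equivalent to one draw from the full noisy kernel).  Capture-time labels
are assigned in blocks along the true time order (earliest block first) —
this is what makes the capture-time-restricted chain initialization
informative — and the cells are returned in shuffled column order together
with the generating permutation.

Three presets are provided: 50 genes and 90 cells each, differing in the
capture-time block structure (three blocks of 30, or blocks of 30 and 60)
and in the noise level (``log sigma_eps`` centred at ``log 0.5`` for the
low-noise designs, at 0 for the high-noise one); all three log-normal laws
have standard deviation 0.1 on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError
from .model import ExpressionMatrix, GPHyperParams

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "simulation_presets",
    "simulate_dataset",
    "write_dataset",
]

@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulation design.

    The ``(mean, sd)`` pairs parametrize normal laws on ``log sigma_w``,
    ``log l`` and ``log sigma_eps`` from which per-gene hyperparameters are
    drawn.  ``metadata`` records the protocol attached to the design
    (dataset count, chain count, iterations, thinning).
    """

    n_genes: int
    n_cells: int
    block_sizes: Tuple[int, ...]
    mean_log_sigma_w: float = 0.0
    sd_log_sigma_w: float = 0.1
    mean_log_l: float = float(np.log(0.4))
    sd_log_l: float = 0.1
    mean_log_sigma_eps: float = float(np.log(0.5))
    sd_log_sigma_eps: float = 0.1
    name: str = "custom"
    metadata: dict = field(
        default_factory=lambda: {
            "n_datasets": 16,
            "n_chains": 5,
            "n_iterations": 100_000,
            "thinning": 10,
        }
    )

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 2:
            raise InvalidInputError("need at least 1 gene and 2 cells")
        if sum(self.block_sizes) != self.n_cells:
            raise InvalidInputError(
                f"block sizes {self.block_sizes} do not sum to {self.n_cells}"
            )
        if min(self.sd_log_sigma_w, self.sd_log_l, self.sd_log_sigma_eps) <= 0:
            raise InvalidInputError("log-normal sds must be positive")


_PRESETS = {
    "sim1": SimulationSpec(50, 90, (30, 30, 30), name="sim1"),
    "sim2": SimulationSpec(50, 90, (30, 60), name="sim2"),
    "sim3": SimulationSpec(
        50, 90, (30, 30, 30), mean_log_sigma_eps=0.0, name="sim3"
    ),
}


def simulation_presets(name: str) -> SimulationSpec:
    """The three published simulation designs (``sim1``, ``sim2``, ``sim3``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None


@dataclass
class SimulatedDataset:
    """A simulated dataset with its generating ground truth.

    ``true_order`` is the permutation that sorts the (shuffled) columns of
    ``expr`` by ascending latent time; ``true_times`` are the latent times
    aligned with the columns of ``expr``.  ``gene_params`` holds the drawn
    ``(sigma_w, l, sigma_eps)`` per gene.
    """

    expr: ExpressionMatrix
    true_order: np.ndarray
    true_times: np.ndarray
    gene_params: np.ndarray
    spec: SimulationSpec

    def gene_hyperparams(self) -> List[GPHyperParams]:
        """Per-gene hyperparameters in the model's variance parametrization."""
        return [
            GPHyperParams(sw**2, l, se**2) for sw, l, se in self.gene_params
        ]


def simulate_dataset(
    spec: SimulationSpec, rng: Union[int, np.random.Generator, None] = None
) -> SimulatedDataset:
    """Draw one dataset from a simulation design."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_g, T = spec.n_genes, spec.n_cells
    times = rng.uniform(0.0, 1.0, size=T)
    sw = np.exp(rng.normal(spec.mean_log_sigma_w, spec.sd_log_sigma_w, size=n_g))
    ls = np.exp(rng.normal(spec.mean_log_l, spec.sd_log_l, size=n_g))
    se = np.exp(
        rng.normal(spec.mean_log_sigma_eps, spec.sd_log_sigma_eps, size=n_g)
    )
    diff2 = (times[None, :] - times[:, None]) ** 2
    values = np.empty((n_g, T))
    for g in range(n_g):
        cov = sw[g] ** 2 * np.exp(-diff2 / (2.0 * ls[g] ** 2))
        cov[np.diag_indices_from(cov)] += 1e-9 * sw[g] ** 2
        chol = np.linalg.cholesky(cov)
        values[g] = chol @ rng.standard_normal(T) + se[g] * rng.standard_normal(T)
    # capture-time labels by blocks along the true time order
    labels_sorted = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    capture = np.empty(T, dtype=int)
    capture[np.argsort(times)] = labels_sorted
    shuffle = rng.permutation(T)
    values = values[:, shuffle]
    times = times[shuffle]
    capture = capture[shuffle]
    expr = ExpressionMatrix(
        values,
        gene_ids=[f"gene_{g:03d}" for g in range(n_g)],
        cell_ids=[f"cell_{c:03d}" for c in range(T)],
        capture_times=capture,
    )
    return SimulatedDataset(
        expr=expr,
        true_order=np.argsort(times),
        true_times=times,
        gene_params=np.column_stack([sw, ls, se]),
        spec=spec,
    )


def write_dataset(ds: SimulatedDataset, out_dir: Union[str, Path]) -> dict:
    """Write a simulated dataset as delimited text files.

    Emits the expression matrix, the capture-time table, the ground truth
    (per-cell latent time and 1-based true position) and the per-gene
    hyperparameters; returns the paths.
    """
    from .io import write_capture_times, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.csv",
        "capture_times": out / "capture_times.csv",
        "truth": out / "truth.csv",
        "gene_params": out / "gene_params.csv",
    }
    write_expression(ds.expr, paths["expression"])
    write_capture_times(ds.expr, paths["capture_times"])
    import pandas as pd

    true_positions = np.argsort(ds.true_order)
    pd.DataFrame(
        {
            "cell_id": ds.expr.cell_ids,
            "true_time": ds.true_times,
            "true_position": true_positions + 1,
        }
    ).to_csv(paths["truth"], index=False)
    pd.DataFrame(
        ds.gene_params,
        columns=["sigma_w", "length_scale", "sigma_eps"],
        index=pd.Index(ds.expr.gene_ids, name="gene_id"),
    ).to_csv(paths["gene_params"])
    return paths
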