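"""Reference protocols for the simulation studies.

These functions wire together the synthetic-data generators, the sampler
and the convergence diagnostics into the two standard benchmark protocols:

* :func:`move3_convergence_study` — segment-reversal move (move 3) only, on
  two-capture-time low-noise data with hyperparameters fixed at their
  generating values and rank-time pseudotimes; reports the corrected
  Gelman-Rubin statistics of the log-likelihood and of the L1 position
  distance to the true order across five chains.
* :func:`adaptive_acceptance_study` — full move mixture with hyperparameter
  sampling and burn-in adaptation on three-capture-time low-noise data;
  reports the realized post-burn-in acceptance rate of the hyperparameter
  block over repeated seeded runs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .convergence import assess
from .model import PriorSpec
from .moves import MoveConfig
from .sampler import run_chains, run_chain
from .synthdata import simulate_dataset, simulation_presets

__all__ = ["move3_convergence_study", "adaptive_acceptance_study"]


def move3_convergence_study(
    n_datasets: int = 3,
    base_seed: int = 1,
    n_iter: int = 100_000,
    thin: int = 10,
    n_chains: int = 5,
    threshold: float = 1.1,
) -> dict:
    """Convergence of move-3-only chains on two-capture-time data.

    For each dataset drawn from the two-capture-time low-noise design
    (blocks of 30 and 60 cells), five chains are run with segment reversal
    as the only order move, per-gene hyperparameters fixed at their
    generating values and rank-time pseudotimes.  Chains start from random
    within-capture-time permutations.  The corrected Gelman-Rubin
    statistics (first half of the thinned samples discarded) are computed
    on the log-likelihood and on the L1 distances of the cell positions to
    the true order, after folding the reversal symmetry using the
    capture-time anchor.

    Returns a dict with the per-dataset statistics and their maximum.
    """
    spec = simulation_presets("sim2")
    per_dataset = []
    for d in range(n_datasets):
        ds_seed = base_seed + d
        ds = simulate_dataset(spec, ds_seed)
        # segment reversal only, plus the standard 0.002 background
        # probability of a full reversal used in all simulation runs
        move_cfg = MoveConfig.defaults(ds.expr.n_cells, p5=0.002, active_moves=(3,))
        chain_seeds = [1000 * ds_seed + k for k in range(n_chains)]
        chains = run_chains(
            ds.expr,
            n_iter,
            chain_seeds,
            thin=thin,
            mode="rank",
            move_cfg=move_cfg,
            fixed_params=ds.gene_hyperparams(),
        )
        report = assess(
            chains,
            reference=ds.true_order,
            threshold=threshold,
            anchor=ds.expr.capture_times,
        )
        per_dataset.append(
            {
                "dataset_seed": ds_seed,
                "rhat_loglik": float(report.rhat_loglik[-1]),
                "rhat_l1": float(report.rhat_l1[-1]),
                "converged": bool(report.converged),
                "n_thinned": int(chains[0].n_stored),
            }
        )
    max_rhat = max(
        max(r["rhat_loglik"], r["rhat_l1"]) for r in per_dataset
    )
    return {
        "max_rhat": float(max_rhat),
        "threshold": threshold,
        "per_dataset": per_dataset,
        "n_thinned": per_dataset[0]["n_thinned"],
    }


def adaptive_acceptance_study(
    n_runs: int = 10,
    base_seed: int = 1,
    n_iter: int = 40_000,
    thin: int = 10,
    dataset_seed: Optional[int] = None,
) -> dict:
    """Post-burn-in hyperparameter acceptance after burn-in adaptation.

    One three-capture-time low-noise dataset is generated; for each of
    ``n_runs`` seeds a single chain is run with the full move mixture,
    hyperparameter sampling enabled and window-100 multiplicative
    adaptation of the proposal standard deviations during the first half of
    the iterations.  Reports the realized acceptance fraction of the
    hyperparameter block over the post-burn-in iterations per run.
    """
    spec = simulation_presets("sim1")
    ds = simulate_dataset(spec, base_seed if dataset_seed is None else dataset_seed)
    prior = PriorSpec.default(ds.expr.total_variance)
    rates = []
    for k in range(n_runs):
        chain = run_chain(
            ds.expr,
            n_iter,
            thin=thin,
            mode="geodesic",
            prior=prior,
            seed=10_000 * base_seed + k,
        )
        rates.append(float(chain.param_acceptance_post))
    return {
        "rates": rates,
        "median": float(np.median(rates)),
        "n_at_least_0.45": int(sum(r >= 0.45 for r in rates)),
        "n_iter": int(n_iter),
    }
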