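"""Metropolis-Hastings sampler over cell orderings and GP hyperparameters.

Each iteration performs one order proposal (drawn from the move mixture,
accepted by the likelihood ratio — the order prior is uniform and all move
kernels are symmetric) followed, when hyperparameter sampling is enabled, by
one joint Gaussian random-walk proposal on ``(log sigma_w2, log l)`` accepted
by likelihood times prior ratio.  Proposal standard deviations are adapted
during burn-in towards an acceptance rate between 0.45 and 0.5 and frozen
afterwards so the post-burn-in chain is a valid time-homogeneous Markov
chain.

For simulation studies the hyperparameters can instead be fixed, either to a
shared parameter set or to per-gene generating values; with rank-time
pseudotimes this admits a fast path that precomputes the covariance inverse
once and evaluates every proposal as a quadratic form.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.linalg import cho_solve

from .exceptions import (
    ConfigurationError,
    ContractViolationError,
    NumericalError,
)
from .model import (
    ExpressionMatrix,
    GPHyperParams,
    PriorSpec,
    cholesky_with_jitter,
    covariance_matrix,
    log_likelihood,
    log_prior,
    rank_pseudotimes,
    sample_prior_params,
)
from .moves import MoveConfig, PairDistanceTable, propose_order

__all__ = [
    "ChainState",
    "ChainSamples",
    "SamplerContext",
    "init_chain",
    "mh_step_order",
    "mh_step_params",
    "adapt_proposals",
    "run_chain",
    "run_chains",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

ParamSpec = Union[GPHyperParams, Sequence[GPHyperParams]]


class _RankFixedLoglik:
    """Quadratic-form likelihood for fixed hyperparameters on rank time.

    Rank pseudotimes do not depend on the ordering, so the covariance (and
    its inverse) is constant along the chain; only the gather of the
    expression columns changes per proposal.
    """

    def __init__(self, values: np.ndarray, params: ParamSpec) -> None:
        self.values = np.ascontiguousarray(values)
        n_g, T = values.shape
        tau = rank_pseudotimes(T)
        if isinstance(params, GPHyperParams):
            chol = cholesky_with_jitter(covariance_matrix(tau, params))
            self.precision = cho_solve((chol, True), np.eye(T), check_finite=False)
            log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
            self.const = -0.5 * n_g * (T * _LOG_2PI + log_det)
            self.per_gene = False
        else:
            params = list(params)
            prec = np.empty((n_g, T, T))
            log_dets = 0.0
            for g, par in enumerate(params):
                chol = cholesky_with_jitter(covariance_matrix(tau, par))
                prec[g] = cho_solve((chol, True), np.eye(T), check_finite=False)
                log_dets += 2.0 * float(np.sum(np.log(np.diag(chol))))
            self.precision = prec
            self.const = -0.5 * (n_g * T * _LOG_2PI + log_dets)
            self.per_gene = True

    def __call__(self, order: np.ndarray) -> float:
        yo = self.values[:, order]
        if self.per_gene:
            quad = float(
                np.sum(np.matmul(self.precision, yo[:, :, None])[:, :, 0] * yo)
            )
        else:
            quad = float(np.sum((yo @ self.precision) * yo))
        return self.const - 0.5 * quad


class SamplerContext:
    """Immutable per-run machinery shared by all chains on one dataset.

    Builds the move configuration, the L1 pair-weight table for moves 2/3,
    the Euclidean distance matrix for geodesic pseudotimes, the prior, and
    (when applicable) the fixed-covariance fast path.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        mode: str = "geodesic",
        move_cfg: Optional[MoveConfig] = None,
        prior: Optional[PriorSpec] = None,
        fixed_params: Optional[ParamSpec] = None,
    ) -> None:
        if mode not in ("geodesic", "rank"):
            raise ConfigurationError(f"unknown pseudotime mode {mode!r}")
        self.expr = expr
        self.mode = mode
        self.move_cfg = move_cfg or MoveConfig.defaults(expr.n_cells)
        p = self.move_cfg.probabilities
        if p[1] + p[2] > 0:
            self.table: Optional[PairDistanceTable] = PairDistanceTable.from_expression(
                expr, gamma=self.move_cfg.gamma, alpha=self.move_cfg.alpha
            )
        else:
            self.table = None
        self.total_variance = expr.total_variance
        self.prior = prior or PriorSpec.default(self.total_variance)
        self.fixed_params = fixed_params
        self.sample_params = fixed_params is None
        self.euclid = expr.cell_distances() if mode == "geodesic" else None
        if fixed_params is not None and mode == "rank":
            self._fast = _RankFixedLoglik(expr.values, fixed_params)
        else:
            self._fast = None

    def loglik(self, order: np.ndarray, params: Optional[ParamSpec]) -> float:
        if self._fast is not None:
            return self._fast(order)
        if params is None:
            params = self.fixed_params
        return log_likelihood(
            self.expr, order, params, mode=self.mode, distances=self.euclid
        )


@dataclass
class ChainState:
    """Mutable state of one MCMC chain."""

    order: np.ndarray
    params: Optional[GPHyperParams]
    log_lik: float
    log_prior: float
    iteration: int
    burn_in: int
    prop_sd: np.ndarray
    move_proposed: np.ndarray
    move_accepted: np.ndarray
    param_proposed: int = 0
    param_accepted: int = 0
    param_proposed_post: int = 0
    param_accepted_post: int = 0
    window_proposed: int = 0
    window_accepted: int = 0

    @property
    def log_posterior(self) -> float:
        return self.log_lik + self.log_prior

    @property
    def in_burn_in(self) -> bool:
        return self.iteration <= self.burn_in


@dataclass
class ChainSamples:
    """Thinned draws of one chain plus acceptance bookkeeping and metadata."""

    orders: np.ndarray
    log_lik: np.ndarray
    log_sigma_w2: np.ndarray
    log_l: np.ndarray
    iterations: np.ndarray
    move_proposed: np.ndarray
    move_accepted: np.ndarray
    param_proposed: int
    param_accepted: int
    param_proposed_post: int
    param_accepted_post: int
    meta: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return self.orders.shape[0]

    @property
    def n_cells(self) -> int:
        return self.orders.shape[1]

    @property
    def param_acceptance_post(self) -> float:
        """Post-burn-in acceptance fraction of the hyperparameter block."""
        if self.param_proposed_post == 0:
            return float("nan")
        return self.param_accepted_post / self.param_proposed_post

    @property
    def config_hash(self) -> str:
        blob = repr(sorted(self.meta.items())).encode()
        return hashlib.md5(blob).hexdigest()[:12]


def start_order(
    expr: ExpressionMatrix, rng: np.random.Generator, restrict: bool = True
) -> np.ndarray:
    """Random starting ordering, by default restricted to permutations of
    cells within (but not across) capture-time blocks, blocks concatenated in
    capture-time order."""
    T = expr.n_cells
    if expr.capture_times is None or not restrict:
        return rng.permutation(T)
    order = np.argsort(expr.capture_times, kind="stable")
    out = np.empty(T, dtype=np.intp)
    pos = 0
    for ct in np.unique(expr.capture_times):
        block = order[expr.capture_times[order] == ct]
        out[pos : pos + len(block)] = rng.permutation(block)
        pos += len(block)
    return out


def init_chain(
    ctx: SamplerContext,
    rng: np.random.Generator,
    n_iter: int,
    burn_in: Optional[int] = None,
    restrict_start: bool = True,
    init_prop_sd: float = 0.1,
    initial_order: Optional[np.ndarray] = None,
) -> ChainState:
    """Initialize a chain with a random (block-restricted) starting order and
    hyperparameters drawn from the prior (unless fixed)."""
    if burn_in is None:
        burn_in = n_iter // 2
    if initial_order is None:
        order = start_order(ctx.expr, rng, restrict=restrict_start)
    else:
        order = np.asarray(initial_order, dtype=np.intp).copy()
    if ctx.sample_params:
        params: Optional[GPHyperParams] = sample_prior_params(
            ctx.prior, ctx.total_variance, rng
        )
        lp = log_prior(params, ctx.prior, ctx.total_variance)
        ll = ctx.loglik(order, params)
    else:
        params = (
            ctx.fixed_params if isinstance(ctx.fixed_params, GPHyperParams) else None
        )
        lp = 0.0
        ll = ctx.loglik(order, params)
    return ChainState(
        order=order,
        params=params,
        log_lik=ll,
        log_prior=lp,
        iteration=0,
        burn_in=burn_in,
        prop_sd=np.full(2, float(init_prop_sd)),
        move_proposed=np.zeros(5, dtype=np.int64),
        move_accepted=np.zeros(5, dtype=np.int64),
    )


def mh_step_order(
    state: ChainState, ctx: SamplerContext, rng: np.random.Generator
) -> ChainState:
    """One Metropolis step on the ordering (symmetric proposal, likelihood
    ratio acceptance)."""
    prop, move_id = propose_order(state.order, ctx.move_cfg, ctx.table, rng)
    llp = ctx.loglik(prop, state.params)
    state.move_proposed[move_id - 1] += 1
    delta = llp - state.log_lik
    if delta >= 0 or np.log(rng.random()) < delta:
        state.order = prop
        state.log_lik = llp
        state.move_accepted[move_id - 1] += 1
    return state


def mh_step_params(
    state: ChainState, ctx: SamplerContext, rng: np.random.Generator
) -> ChainState:
    """One block Metropolis step on ``(log sigma_w2, log l)``.

    Proposals with ``sigma_w2 >= V`` fall outside the prior support and are
    rejected without a likelihood evaluation.
    """
    if not ctx.sample_params or state.params is None:
        raise ConfigurationError("hyperparameter sampling is disabled for this run")
    state.param_proposed += 1
    state.window_proposed += 1
    post = not state.in_burn_in
    if post:
        state.param_proposed_post += 1

    def _accept() -> None:
        state.param_accepted += 1
        state.window_accepted += 1
        if post:
            state.param_accepted_post += 1

    if np.all(state.prop_sd == 0):
        _accept()
        return state
    z = np.array([state.params.log_sigma_w2, state.params.log_l])
    zp = z + state.prop_sd * rng.standard_normal(2)
    sigma_w2 = float(np.exp(zp[0]))
    if sigma_w2 >= ctx.total_variance:
        return state
    prop = GPHyperParams.from_total_variance(
        sigma_w2, float(np.exp(zp[1])), ctx.total_variance
    )
    llp = ctx.loglik(state.order, prop)
    lpp = log_prior(prop, ctx.prior, ctx.total_variance)
    delta = (llp + lpp) - (state.log_lik + state.log_prior)
    if delta >= 0 or np.log(rng.random()) < delta:
        state.params = prop
        state.log_lik = llp
        state.log_prior = lpp
        _accept()
    return state


def adapt_proposals(
    state: ChainState, window_acceptance: float, up: float = 1.1, down: float = 0.9
) -> ChainState:
    """Rescale hyperparameter proposal sds from a windowed acceptance rate.

    Aims at acceptance between 0.45 and 0.5: the sds grow by ``up`` above
    0.5, shrink by ``down`` below 0.45 and stay put inside the window.  Only
    legal during burn-in; afterwards the proposal must stay frozen for the
    chain to remain a valid MCMC sampler.
    """
    if not state.in_burn_in:
        raise ContractViolationError("proposal adaptation is only allowed in burn-in")
    if window_acceptance > 0.5:
        state.prop_sd = state.prop_sd * up
    elif window_acceptance < 0.45:
        state.prop_sd = state.prop_sd * down
    return state


def run_chain(
    expr: ExpressionMatrix,
    n_iter: int,
    thin: int = 10,
    burn_in: Optional[int] = None,
    mode: str = "geodesic",
    move_cfg: Optional[MoveConfig] = None,
    prior: Optional[PriorSpec] = None,
    fixed_params: Optional[ParamSpec] = None,
    restrict_start: bool = True,
    init_prop_sd: float = 0.1,
    adapt_window: int = 100,
    seed: int = 0,
    initial_order: Optional[np.ndarray] = None,
    ctx: Optional[SamplerContext] = None,
) -> ChainSamples:
    """Run one chain and return its thinned samples.

    Deterministic given ``seed``.  ``burn_in`` defaults to half the
    iterations.  ``fixed_params`` disables hyperparameter sampling (a single
    shared :class:`GPHyperParams` or one per gene); otherwise parameters are
    initialized from the prior and sampled jointly with the ordering.
    """
    if thin < 1 or n_iter < thin:
        raise ConfigurationError("need n_iter >= thin >= 1")
    if ctx is None:
        ctx = SamplerContext(
            expr, mode=mode, move_cfg=move_cfg, prior=prior, fixed_params=fixed_params
        )
    mode = ctx.mode
    rng = np.random.default_rng(seed)
    state = init_chain(
        ctx,
        rng,
        n_iter,
        burn_in=burn_in,
        restrict_start=restrict_start,
        init_prop_sd=init_prop_sd,
        initial_order=initial_order,
    )
    T = expr.n_cells
    n_stored = n_iter // thin
    orders = np.empty((n_stored, T), dtype=np.int32)
    ll_trace = np.empty(n_stored)
    lsw_trace = np.full(n_stored, np.nan)
    ll_scale_trace = np.full(n_stored, np.nan)
    iters = np.empty(n_stored, dtype=np.int64)
    stored = 0
    sd_history: list = []
    for it in range(1, n_iter + 1):
        state.iteration = it
        try:
            mh_step_order(state, ctx, rng)
            if ctx.sample_params:
                mh_step_params(state, ctx, rng)
                if state.in_burn_in and state.window_proposed >= adapt_window:
                    adapt_proposals(
                        state, state.window_accepted / state.window_proposed
                    )
                    state.window_proposed = 0
                    state.window_accepted = 0
                    sd_history.append(np.log(state.prop_sd))
                if it == state.burn_in and len(sd_history) >= 2:
                    # Freeze at the geometric mean of the adapted sds over the
                    # second half of burn-in: the window-100 acceptance
                    # estimates are noisy, so the last raw sd can sit a step
                    # or two off target; averaging removes that jitter.
                    tail = np.asarray(sd_history[len(sd_history) // 2 :])
                    state.prop_sd = np.exp(tail.mean(axis=0))
        except NumericalError as exc:
            raise NumericalError(f"iteration {it}: {exc}") from None
        if it % thin == 0:
            orders[stored] = state.order
            ll_trace[stored] = state.log_lik
            if state.params is not None:
                lsw_trace[stored] = state.params.log_sigma_w2
                ll_scale_trace[stored] = state.params.log_l
            iters[stored] = it
            stored += 1
    cfg = ctx.move_cfg
    meta = {
        "seed": int(seed),
        "n_iter": int(n_iter),
        "thin": int(thin),
        "burn_in": int(state.burn_in),
        "mode": mode,
        "sample_params": bool(ctx.sample_params),
        "restrict_start": bool(restrict_start),
        "probabilities": tuple(cfg.probabilities),
        "n0": cfg.n0,
        "n3": cfg.n3,
        "n3a": cfg.n3a,
        "gamma": None if ctx.table is None else ctx.table.gamma,
        "alpha": cfg.alpha,
        "final_prop_sd": tuple(float(s) for s in state.prop_sd),
    }
    return ChainSamples(
        orders=orders,
        log_lik=ll_trace,
        log_sigma_w2=lsw_trace,
        log_l=ll_scale_trace,
        iterations=iters,
        move_proposed=state.move_proposed,
        move_accepted=state.move_accepted,
        param_proposed=state.param_proposed,
        param_accepted=state.param_accepted,
        param_proposed_post=state.param_proposed_post,
        param_accepted_post=state.param_accepted_post,
        meta=meta,
    )


def run_chains(
    expr: ExpressionMatrix,
    n_iter: int,
    seeds: Sequence[int],
    **kwargs,
) -> List[ChainSamples]:
    """Run independent chains, one per seed (seeds must be distinct).

    Chains share the immutable sampler context (distance tables, fixed
    covariance inverses) but are otherwise fully independent; execution
    order does not affect any chain's output.
    """
    seeds = [int(s) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise ConfigurationError(f"duplicate chain seeds: {seeds}")
    ctx = SamplerContext(
        expr,
        mode=kwargs.get("mode", "geodesic"),
        move_cfg=kwargs.pop("move_cfg", None),
        prior=kwargs.pop("prior", None),
        fixed_params=kwargs.pop("fixed_params", None),
    )
    kwargs.pop("mode", None)
    return [run_chain(expr, n_iter, seed=s, ctx=ctx, **kwargs) for s in seeds]
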