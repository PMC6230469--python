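"""Gaussian-process model of expression trajectories over cell orderings.

Each gene's log-expression profile, read along a candidate ordering of the
cells, is modelled as a draw from a zero-mean Gaussian process with a squared
exponential covariance

    Sigma_ij = sigma_w^2 * exp(-(tau_j - tau_i)^2 / (2 l^2)) + delta_ij * sigma_eps^2

where ``tau`` is a pseudotime vector derived deterministically from the
ordering (geodesic or rank mapping), ``sigma_w^2`` the signal variance,
``l`` the length scale and ``sigma_eps^2`` iid measurement noise.  All genes
share one covariance matrix; the marginal likelihood of the expression matrix
given an ordering is the product of the per-gene multivariate normal
densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cholesky as _sp_cholesky
from scipy.linalg import solve_triangular
from scipy.spatial.distance import pdist, squareform

from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    InvalidInputError,
    NumericalError,
)

__all__ = [
    "ExpressionMatrix",
    "GPHyperParams",
    "PriorSpec",
    "Ordering",
    "covariance_matrix",
    "cholesky_with_jitter",
    "geodesic_pseudotimes",
    "rank_pseudotimes",
    "log_likelihood",
    "log_prior",
    "sample_prior_params",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ExpressionMatrix:
    """Log-transformed expression values, genes in rows and cells in columns.

    ``capture_times`` are optional per-cell labels (numeric or ordered
    strings) recording the experimental time point at which each cell was
    destructively measured.
    """

    values: np.ndarray
    gene_ids: Sequence[str]
    cell_ids: Sequence[str]
    capture_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("expression values contain non-finite entries")
        n_g, T = self.values.shape
        if n_g < 1 or T < 2:
            raise InvalidInputError(
                f"need at least 1 gene and 2 cells, got {n_g} x {T}"
            )
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if len(self.gene_ids) != n_g:
            raise InvalidInputError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != T:
            raise InvalidInputError("cell_ids length does not match matrix columns")
        if self.capture_times is not None:
            self.capture_times = np.asarray(self.capture_times)
            if self.capture_times.shape != (T,):
                raise InvalidInputError("capture_times must have one entry per cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def total_variance(self) -> float:
        """Sample variance of the flattened genes-by-cells matrix (``V``)."""
        return float(np.var(self.values, ddof=1))

    def cell_distances(self, metric: str = "euclidean") -> np.ndarray:
        """Square matrix of pairwise distances between cells."""
        return squareform(pdist(self.values.T, metric=metric))

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[index],
            [self.gene_ids[i] for i in index],
            self.cell_ids,
            self.capture_times,
        )


@dataclass(frozen=True)
class GPHyperParams:
    """Squared-exponential kernel hyperparameters.

    ``sigma_eps2`` is kept explicit so that fixed configurations (e.g. the
    generating values of a simulation) can decouple noise from total
    variance; when hyperparameters are sampled the model ties
    ``sigma_eps2 = V - sigma_w2``.
    """

    sigma_w2: float
    length_scale: float
    sigma_eps2: float

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.sigma_w2)
            and np.isfinite(self.length_scale)
            and np.isfinite(self.sigma_eps2)
        ):
            raise InvalidInputError("hyperparameters must be finite")
        if self.sigma_w2 <= 0 or self.length_scale <= 0 or self.sigma_eps2 <= 0:
            raise InvalidInputError(
                "sigma_w2, length_scale and sigma_eps2 must all be positive "
                f"(got {self.sigma_w2}, {self.length_scale}, {self.sigma_eps2})"
            )

    @classmethod
    def from_total_variance(
        cls, sigma_w2: float, length_scale: float, total_variance: float
    ) -> "GPHyperParams":
        """Build parameters under the variance split ``sigma_eps2 = V - sigma_w2``."""
        return cls(sigma_w2, length_scale, total_variance - sigma_w2)

    @property
    def log_sigma_w2(self) -> float:
        return float(np.log(self.sigma_w2))

    @property
    def log_l(self) -> float:
        return float(np.log(self.length_scale))


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the log signal variance and log length scale.

    Defaults place the signal variance near ``0.9 V`` (so the implied noise
    term ``V - sigma_w2`` is about a tenth of the total variance, reflecting
    comparatively low measurement noise) and the length scale near ``1/2`` on
    the unit pseudotime interval.  Standard deviations are ``sqrt(0.01) = 0.1``
    on the log scale: a deliberately strong prior, since with a vague one the
    posterior length scale shrinks and the GP overfits noisy single-cell data.
    """

    mean_log_sigma_w2: float
    sd_log_sigma_w2: float = 0.1
    mean_log_l: float = float(np.log(0.5))
    sd_log_l: float = 0.1

    def __post_init__(self) -> None:
        if self.sd_log_sigma_w2 <= 0 or self.sd_log_l <= 0:
            raise InvalidInputError("prior standard deviations must be positive")

    @classmethod
    def default(
        cls, total_variance: float, parametrization: str = "sigma_w2"
    ) -> "PriorSpec":
        """Default prior given the data's total variance ``V``.

        ``parametrization='sigma_w2'`` (default) centres ``log sigma_w2`` at
        ``log(0.9 V)``.  ``parametrization='sigma_w'`` instead centres
        ``log sigma_w`` at ``log(0.9 V)``, i.e. ``log sigma_w2`` at
        ``2 log(0.9 V)`` with doubled sd; note this interpretation leaves the
        support constraint ``sigma_w2 < V`` unsatisfiable for ``V > 1.23``.
        """
        if total_variance <= 0:
            raise InvalidInputError("total variance must be positive")
        m = float(np.log(0.9 * total_variance))
        if parametrization == "sigma_w2":
            return cls(mean_log_sigma_w2=m)
        if parametrization == "sigma_w":
            return cls(mean_log_sigma_w2=2.0 * m, sd_log_sigma_w2=0.2)
        raise ConfigurationError(f"unknown prior parametrization {parametrization!r}")


def rank_pseudotimes(n_cells: int) -> np.ndarray:
    """Equidistant pseudotimes ``(i - 0.5) / T`` for ``i = 1..T``."""
    if n_cells < 1:
        raise InvalidInputError("need at least one cell")
    return (np.arange(1, n_cells + 1) - 0.5) / n_cells


def geodesic_pseudotimes(
    expr: ExpressionMatrix, order: np.ndarray, distances: Optional[np.ndarray] = None
) -> np.ndarray:
    """Map an ordering to pseudotimes by cumulative consecutive-cell distances.

    The j-th pseudotime is the sum of Euclidean distances (in gene-expression
    space) between cells ranked next to each other up to position j, scaled so
    the last cell sits at 1.  Cells with similar profiles end up close in
    pseudotime; dissimilar neighbours are spread apart.

    ``distances`` may supply a precomputed square Euclidean distance matrix.
    """
    order = _check_permutation(order, expr.n_cells)
    if distances is None:
        steps = np.linalg.norm(
            expr.values[:, order[1:]] - expr.values[:, order[:-1]], axis=0
        )
    else:
        steps = distances[order[:-1], order[1:]]
    tau = np.concatenate(([0.0], np.cumsum(steps)))
    total = tau[-1]
    if total <= 0:
        raise DegenerateDataError(
            "all consecutive cells are identical; geodesic pseudotimes undefined"
        )
    return tau / total


@dataclass
class Ordering:
    """A permutation of cell indices with its derived pseudotime vector."""

    positions: np.ndarray
    pseudotimes: np.ndarray

    @classmethod
    def from_permutation(
        cls, expr: ExpressionMatrix, order: np.ndarray, mode: str = "geodesic"
    ) -> "Ordering":
        order = _check_permutation(order, expr.n_cells)
        if mode == "geodesic":
            tau = geodesic_pseudotimes(expr, order)
        elif mode == "rank":
            tau = rank_pseudotimes(expr.n_cells)
        else:
            raise ConfigurationError(f"unknown pseudotime mode {mode!r}")
        return cls(order, tau)


def covariance_matrix(tau: np.ndarray, params: GPHyperParams) -> np.ndarray:
    """Squared-exponential covariance over pseudotimes plus diagonal noise."""
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 1 or not np.all(np.isfinite(tau)):
        raise InvalidInputError("tau must be a finite 1-D vector")
    diff = tau[None, :] - tau[:, None]
    cov = params.sigma_w2 * np.exp(diff * diff / (-2.0 * params.length_scale**2))
    cov[np.diag_indices_from(cov)] += params.sigma_eps2
    return cov


def cholesky_with_jitter(cov: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, escalating diagonal jitter on failure.

    Jitter starts at ``1e-10 * trace/T`` and grows tenfold up to
    ``1e-6 * trace/T`` before giving up.
    """
    scale = float(np.trace(cov)) / cov.shape[0]
    try:
        return _sp_cholesky(cov, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-10 * scale
    eye = np.eye(cov.shape[0])
    while jitter <= 1e-6 * scale * (1 + 1e-12):
        try:
            return _sp_cholesky(cov + jitter * eye, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise NumericalError(
        "covariance matrix not positive definite even with jitter "
        f"{1e-6 * scale:.3e} (trace/T = {scale:.3e})"
    )


def _check_permutation(order: np.ndarray, n: int) -> np.ndarray:
    order = np.asarray(order)
    if order.shape != (n,) or not np.array_equal(np.sort(order), np.arange(n)):
        raise InvalidInputError(f"order must be a permutation of 0..{n - 1}")
    return order.astype(np.intp, copy=False)


def log_likelihood(
    expr: ExpressionMatrix,
    order: np.ndarray,
    params,
    mode: str = "geodesic",
    distances: Optional[np.ndarray] = None,
) -> float:
    """Marginal log-likelihood of the expression matrix given an ordering.

    Sums the zero-mean multivariate normal log-density of every gene's
    profile, reordered by ``order``, under the covariance built from the
    ordering's pseudotimes.  ``params`` is normally a single
    :class:`GPHyperParams` shared by all genes (one Cholesky factorization is
    reused across genes); a sequence of ``n_genes`` parameter sets evaluates
    gene-specific covariances instead, as needed when fixing hyperparameters
    to per-gene generating values in simulation studies.
    """
    order = _check_permutation(order, expr.n_cells)
    if mode == "geodesic":
        tau = geodesic_pseudotimes(expr, order, distances=distances)
    elif mode == "rank":
        tau = rank_pseudotimes(expr.n_cells)
    else:
        raise ConfigurationError(f"unknown pseudotime mode {mode!r}")
    y = expr.values[:, order]
    n_g, T = y.shape
    if isinstance(params, GPHyperParams):
        chol = _factorize(tau, params)
        z = solve_triangular(chol, y.T, lower=True, check_finite=False)
        log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
        return -0.5 * (n_g * T * _LOG_2PI + n_g * log_det + float(np.sum(z * z)))
    params = list(params)
    if len(params) != n_g:
        raise InvalidInputError(
            f"got {len(params)} per-gene parameter sets for {n_g} genes"
        )
    total = 0.0
    for g, par in enumerate(params):
        chol = _factorize(tau, par)
        z = solve_triangular(chol, y[g], lower=True, check_finite=False)
        log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
        total += -0.5 * (T * _LOG_2PI + log_det + float(np.sum(z * z)))
    return total


def _factorize(tau: np.ndarray, params: GPHyperParams) -> np.ndarray:
    cov = covariance_matrix(tau, params)
    try:
        return cholesky_with_jitter(cov)
    except NumericalError as exc:
        raise NumericalError(
            f"{exc} [sigma_w2={params.sigma_w2:.4g}, l={params.length_scale:.4g}, "
            f"sigma_eps2={params.sigma_eps2:.4g}]"
        ) from None


def log_prior(params: GPHyperParams, spec: PriorSpec, total_variance: float) -> float:
    """Log prior density of the hyperparameters on the log scale.

    Returns ``-inf`` when ``sigma_w2 >= V`` (outside the support implied by
    the variance split).  The uniform prior over orderings contributes a
    constant and is omitted.
    """
    if params.sigma_w2 >= total_variance:
        return -np.inf
    lp = 0.0
    for x, m, s in (
        (params.log_sigma_w2, spec.mean_log_sigma_w2, spec.sd_log_sigma_w2),
        (params.log_l, spec.mean_log_l, spec.sd_log_l),
    ):
        lp += -0.5 * ((x - m) / s) ** 2 - np.log(s) - 0.5 * _LOG_2PI
    return float(lp)


def sample_prior_params(
    spec: PriorSpec,
    total_variance: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> GPHyperParams:
    """Draw hyperparameters from the prior, rejecting draws with ``sigma_w2 >= V``."""
    if total_variance <= 0:
        raise InvalidInputError("total variance must be positive")
    for _ in range(max_tries):
        log_sw2 = rng.normal(spec.mean_log_sigma_w2, spec.sd_log_sigma_w2)
        log_l = rng.normal(spec.mean_log_l, spec.sd_log_l)
        sigma_w2 = float(np.exp(log_sw2))
        if sigma_w2 < total_variance:
            return GPHyperParams.from_total_variance(
                sigma_w2, float(np.exp(log_l)), total_variance
            )
    raise ConfigurationError(
        "could not draw sigma_w2 < V from the prior after "
        f"{max_tries} tries; prior mean exp({spec.mean_log_sigma_w2:.3g}) "
        f"is inconsistent with V = {total_variance:.3g}"
    )
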