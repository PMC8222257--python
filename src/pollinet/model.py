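"""Core model quantities: data types, likelihood, priors, and the marginal posterior.

The observation model treats the visitation count for each plant--pollinator
pair as a Poisson variable whose mean is ``C * sigma_i * tau_j * (1 + r * B_ij)``,
where ``B`` is the latent binary incidence matrix of preferred interactions.
Because the posterior factorizes over entries of ``B``, the sum over all
``2**(n_p*n_a)`` incidence matrices can be carried out analytically, yielding a
marginal posterior over the continuous parameters alone.  All posterior
evaluations here work in log space with a branch-stable log-sum-exp so that
extreme counts, preferences, and sampling efforts do not overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "VisitationMatrix",
    "IncidenceMatrix",
    "ModelParameters",
    "PriorConfig",
    "compute_mean_matrix",
    "log_likelihood",
    "log_posterior_joint",
    "log_marginal_posterior",
    "log_branch_terms",
]

#: tolerance accepted on input simplex sums before renormalization
_SIMPLEX_TOL = 1e-6


def _default_labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{k + 1}" for k in range(n)]


def _check_labels(labels: list[str], n: int, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"{what}: {len(labels)} labels for {n} rows/columns")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what}: duplicate labels")
    return labels


@dataclass(frozen=True)
class VisitationMatrix:
    """Observed visitation counts ``M`` with species labels.

    Parameters
    ----------
    counts
        ``(n_p, n_a)`` array of non-negative integers; entry ``(i, j)`` is the
        number of recorded visits of pollinator species ``j`` to plant
        species ``i``.
    plant_labels, pollinator_labels
        Unique species names; generated (``P1..``, ``A1..``) when omitted.
    """

    counts: np.ndarray
    plant_labels: list[str] = field(default=None)  # type: ignore[assignment]
    pollinator_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("counts must be a 2-d matrix with at least one row and column")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64, casting="unsafe")
            if not np.array_equal(as_int, counts):
                raise ValueError("counts must be integers")
            counts = as_int
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        n_p, n_a = counts.shape
        plants = self.plant_labels if self.plant_labels is not None else _default_labels("P", n_p)
        pols = (
            self.pollinator_labels
            if self.pollinator_labels is not None
            else _default_labels("A", n_a)
        )
        object.__setattr__(self, "plant_labels", _check_labels(plants, n_p, "plant_labels"))
        object.__setattr__(
            self, "pollinator_labels", _check_labels(pols, n_a, "pollinator_labels")
        )
        if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
            warnings.warn(
                "visitation matrix contains species with zero recorded visits; "
                "their abundance parameters are weakly identified",
                stacklevel=2,
            )

    @property
    def n_plants(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pollinators(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        """Total number of recorded visits."""
        return int(self.counts.sum())

    def observations_per_pair(self) -> float:
        """Average number of observations per plant-pollinator species pair."""
        return self.total / (self.n_plants * self.n_pollinators)


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary incidence matrix ``B`` of a bipartite network of preferred interactions."""

    entries: np.ndarray
    plant_labels: list[str] = field(default=None)  # type: ignore[assignment]
    pollinator_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.ndim != 2 or entries.shape[0] < 1 or entries.shape[1] < 1:
            raise ValueError("entries must be a 2-d matrix with at least one row and column")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("entries must be exactly 0 or 1")
        object.__setattr__(self, "entries", entries.astype(np.int8))
        n_p, n_a = entries.shape
        plants = self.plant_labels if self.plant_labels is not None else _default_labels("P", n_p)
        pols = (
            self.pollinator_labels
            if self.pollinator_labels is not None
            else _default_labels("A", n_a)
        )
        object.__setattr__(self, "plant_labels", _check_labels(plants, n_p, "plant_labels"))
        object.__setattr__(
            self, "pollinator_labels", _check_labels(pols, n_a, "pollinator_labels")
        )

    @property
    def n_plants(self) -> int:
        return self.entries.shape[0]

    @property
    def n_pollinators(self) -> int:
        return self.entries.shape[1]

    @property
    def n_edges(self) -> int:
        return int(self.entries.sum())


@dataclass(frozen=True)
class ModelParameters:
    """Continuous model parameters ``(C, r, rho, sigma, tau)``.

    ``C`` is the global sampling-effort scale, ``r >= 0`` the preference factor
    (preferred pairs are visited ``1 + r`` times more often), ``rho`` the prior
    edge probability (connectance), and ``sigma``/``tau`` the relative plant
    and pollinator abundances, each normalized to sum to one.
    """

    C: float
    r: float
    rho: float
    sigma: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.C) or self.C < 0:
            raise ValueError("C must be finite and >= 0")
        if not np.isfinite(self.r) or self.r < 0:
            raise ValueError("r must be finite and >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        for name in ("sigma", "tau"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.ndim != 1 or vec.size < 1:
                raise ValueError(f"{name} must be a 1-d vector")
            if (vec < 0).any():
                raise ValueError(f"{name} must be non-negative")
            total = vec.sum()
            if abs(total - 1.0) > _SIMPLEX_TOL:
                raise ValueError(f"{name} must sum to 1 (got {total!r})")
            object.__setattr__(self, name, vec / total)

    @property
    def n_plants(self) -> int:
        return self.sigma.size

    @property
    def n_pollinators(self) -> int:
        return self.tau.size


@dataclass(frozen=True)
class PriorConfig:
    """Prior settings: exponential rate on ``r`` and optional upper bound on ``C``.

    The prior on ``C`` is uniform; with ``c_upper=None`` it is the improper
    flat density on ``(0, inf)`` (the posterior remains proper because the
    marginal posterior carries an ``exp(-C)`` factor).
    """

    lambda_r: float = 0.01
    c_upper: float | None = None

    def __post_init__(self) -> None:
        if not self.lambda_r > 0:
            raise ValueError("lambda_r must be positive")
        if self.c_upper is not None and not self.c_upper > 0:
            raise ValueError("c_upper must be positive when given")


def _check_shapes(*objs) -> tuple[int, int]:
    shapes = {(o.n_plants, o.n_pollinators) for o in objs}
    if len(shapes) != 1:
        raise ValueError(f"dimension mismatch: {sorted(shapes)}")
    return shapes.pop()


def compute_mean_matrix(params: ModelParameters, network: IncidenceMatrix) -> np.ndarray:
    """Expected visit counts ``C * sigma_i * tau_j * (1 + r * B_ij)``."""
    _check_shapes(params, network)
    base = params.C * np.outer(params.sigma, params.tau)
    return base * (1.0 + params.r * network.entries)


def log_likelihood(
    data: VisitationMatrix, network: IncidenceMatrix, params: ModelParameters
) -> float:
    """Exact log probability of the full count matrix given network and parameters.

    Sum of independent Poisson log-pmfs; ``exp`` of the result is a true
    probability.  A zero mean paired with a positive count yields ``-inf``.
    """
    _check_shapes(data, network, params)
    mu = compute_mean_matrix(params, network)
    m = data.counts
    if ((mu == 0) & (m > 0)).any():
        return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(m > 0, m * np.log(np.where(mu > 0, mu, 1.0)), 0.0)
    return float(term.sum() - mu.sum() - gammaln(m + 1.0).sum())


def _log_bernoulli_prior(network: IncidenceMatrix, rho: float) -> float:
    b = network.entries
    n_edges = int(b.sum())
    n_non = b.size - n_edges
    with np.errstate(divide="ignore"):
        log_rho = np.log(rho) if rho > 0 else -np.inf
        log_1m = np.log1p(-rho) if rho < 1 else -np.inf
    if n_edges and np.isneginf(log_rho):
        return float("-inf")
    if n_non and np.isneginf(log_1m):
        return float("-inf")
    return n_edges * (log_rho if n_edges else 0.0) + n_non * (log_1m if n_non else 0.0)


def log_posterior_joint(
    data: VisitationMatrix,
    network: IncidenceMatrix,
    params: ModelParameters,
    prior: PriorConfig | None = None,
) -> float:
    """Log of the joint posterior over ``(B, theta)`` up to a data-only constant.

    Composed as ``log_likelihood + Bernoulli edge prior + exponential prior on r``
    (flat priors on ``C``, ``rho`` and the abundance simplexes contribute
    nothing beyond support constraints).
    """
    prior = prior or PriorConfig()
    if prior.c_upper is not None and params.C > prior.c_upper:
        return float("-inf")
    ll = log_likelihood(data, network, params)
    edge_prior = _log_bernoulli_prior(network, params.rho)
    r_prior = np.log(prior.lambda_r) - prior.lambda_r * params.r
    return float(ll + edge_prior + r_prior)


def log_branch_terms(
    data: VisitationMatrix | np.ndarray, params: ModelParameters
) -> tuple[float, np.ndarray]:
    """Log-branch terms ``(a, b_ij)`` of the per-entry edge marginalization.

    ``a = log(1 - rho)`` collects the no-edge branch and
    ``b_ij = log(rho) + M_ij*log(1 + r) - C*r*sigma_i*tau_j`` the edge branch,
    so that ``logaddexp(a, b_ij)`` is the stable log of
    ``1 - rho + rho*(1+r)**M_ij * exp(-C*sigma_i*tau_j*r)``.
    """
    m = data.counts if isinstance(data, VisitationMatrix) else np.asarray(data)
    with np.errstate(divide="ignore"):
        a = np.log1p(-params.rho) if params.rho < 1 else float("-inf")
        log_rho = np.log(params.rho) if params.rho > 0 else float("-inf")
    b = log_rho + m * np.log1p(params.r) - params.C * params.r * np.outer(
        params.sigma, params.tau
    )
    return a, b


def log_marginal_posterior(
    params: ModelParameters,
    data: VisitationMatrix,
    prior: PriorConfig | None = None,
) -> float:
    """Log posterior density of the parameters with the incidence matrix summed out.

    Up to an additive constant (the ``log M_ij!`` terms are dropped; they are
    identical for every parameter value), this is::

        -C + log P(r) + sum_ij [ M_ij * log(C * sigma_i * tau_j) + Y_ij ]

    with ``Y_ij = logaddexp(a, b_ij)`` from :func:`log_branch_terms`.
    Returns ``-inf`` when a zero abundance (or ``C = 0``) meets a positive count.
    """
    prior = prior or PriorConfig()
    _check_shapes(data, params)
    if prior.c_upper is not None and params.C > prior.c_upper:
        return float("-inf")
    m = data.counts
    base = params.C * np.outer(params.sigma, params.tau)
    if ((base == 0) & (m > 0)).any():
        return float("-inf")
    with np.errstate(divide="ignore"):
        x = np.where(m > 0, m * np.log(np.where(base > 0, base, 1.0)), 0.0)
    a, b = log_branch_terms(data, params)
    y = np.logaddexp(a, b)
    r_prior = np.log(prior.lambda_r) - prior.lambda_r * params.r
    return float(-params.C + r_prior + x.sum() + y.sum())
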