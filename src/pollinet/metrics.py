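"""Network summary statistics on single networks and over the posterior.

All metrics accept a plain :class:`~pollinet.model.IncidenceMatrix`; posterior
distributions of any metric are obtained by pushing it through
:func:`~pollinet.inference.posterior_average` (see :func:`posterior_metric`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import EdgeProbabilityMatrix, ParameterDraws, posterior_average
from .model import IncidenceMatrix, VisitationMatrix

__all__ = [
    "MetricDistribution",
    "threshold_network",
    "connectance",
    "nodf",
    "degree_distribution",
    "mean_degree",
    "aggregate",
    "posterior_metric",
]


@dataclass(frozen=True)
class MetricDistribution:
    """Posterior samples of a scalar network metric with summary statistics."""

    samples: np.ndarray
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "MetricDistribution":
        s = np.asarray(samples, dtype=float)
        lo, hi = np.percentile(s, [2.5, 97.5])
        return cls(
            samples=s,
            mean=float(s.mean()),
            sd=float(s.std(ddof=1)) if len(s) > 1 else 0.0,
            ci_low=float(lo),
            ci_high=float(hi),
        )

    def to_report(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_samples": int(len(self.samples)),
        }


def threshold_network(data: VisitationMatrix, t: int = 1) -> IncidenceMatrix:
    """Naive binary network: an edge wherever the count reaches the threshold ``t``."""
    if t < 1:
        raise ValueError("threshold must be a positive integer")
    return IncidenceMatrix(
        entries=(data.counts >= t).astype(np.int8),
        plant_labels=data.plant_labels,
        pollinator_labels=data.pollinator_labels,
    )


def connectance(network: IncidenceMatrix) -> float:
    """Fraction of realized edges among all plant-pollinator pairs."""
    return float(network.entries.mean())


def nodf(network: IncidenceMatrix) -> float:
    """Nestedness based on Overlap and Decreasing Fill, on the 0-100 scale.

    For every pair of rows ``(u, v)`` with degrees ``k_u > k_v > 0`` the pair
    contributes ``100 * |N(u) & N(v)| / k_v``; pairs with equal degrees or a
    zero-degree member contribute 0 (the decreasing-fill requirement).  Same
    over column pairs; the total is divided by the number of row pairs plus
    column pairs.
    """
    b = network.entries.astype(np.int64)
    n_p, n_a = b.shape
    n_pairs = n_p * (n_p - 1) // 2 + n_a * (n_a - 1) // 2
    if n_pairs == 0:
        raise ValueError("NODF undefined for a single-row, single-column network")

    def side_score(mat: np.ndarray) -> float:
        deg = mat.sum(axis=1)
        overlap = mat @ mat.T
        ku = deg[:, None]
        kv = deg[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where((ku > kv) & (kv > 0), overlap / np.where(kv > 0, kv, 1), 0.0)
        return float(scores.sum())  # each unordered pair counted once (one ordering wins)

    return 100.0 * (side_score(b) + side_score(b.T)) / n_pairs


def _side_degrees(network: IncidenceMatrix, side: str) -> np.ndarray:
    if side == "plants":
        return network.entries.sum(axis=1)
    if side == "pollinators":
        return network.entries.sum(axis=0)
    raise ValueError("side must be 'plants' or 'pollinators'")


def degree_distribution(network: IncidenceMatrix, side: str = "plants") -> np.ndarray:
    """Fraction ``p_k`` of nodes on one side with degree exactly ``k`` (k = 0..max)."""
    deg = _side_degrees(network, side)
    counts = np.bincount(deg)
    return counts / counts.sum()


def mean_degree(edge_probs: EdgeProbabilityMatrix, side: str = "plants") -> float:
    """Posterior-expected mean degree: total edge probability per node on one side."""
    total = edge_probs.probabilities.sum()
    if side == "plants":
        return float(total / edge_probs.n_plants)
    if side == "pollinators":
        return float(total / edge_probs.n_pollinators)
    raise ValueError("side must be 'plants' or 'pollinators'")


def aggregate(matrices: list[VisitationMatrix]) -> VisitationMatrix:
    """Sum visitation matrices over the union of their species, matched by label."""
    if not matrices:
        raise ValueError("need at least one matrix")
    plants: list[str] = []
    pols: list[str] = []
    for vm in matrices:
        plants.extend(l for l in vm.plant_labels if l not in plants)
        pols.extend(l for l in vm.pollinator_labels if l not in pols)
    out = np.zeros((len(plants), len(pols)), dtype=np.int64)
    p_index = {l: i for i, l in enumerate(plants)}
    a_index = {l: j for j, l in enumerate(pols)}
    for vm in matrices:
        rows = [p_index[l] for l in vm.plant_labels]
        cols = [a_index[l] for l in vm.pollinator_labels]
        out[np.ix_(rows, cols)] += vm.counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-count species warning re-raised downstream
        return VisitationMatrix(counts=out, plant_labels=plants, pollinator_labels=pols)


def posterior_metric(
    metric,
    draws: ParameterDraws,
    data: VisitationMatrix,
    n_networks_per_draw: int = 1,
    seed: int = 0,
) -> MetricDistribution:
    """Posterior distribution of a network metric via joint (B, theta) sampling."""
    est = posterior_average(
        lambda b, theta: metric(b), draws, data, n_networks_per_draw, seed
    )
    return MetricDistribution.from_samples(est.values)
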