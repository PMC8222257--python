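"""Posterior-predictive model checking: predictive means, residues, discrepancy."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import ParameterDraws, edge_probability
from .model import VisitationMatrix

__all__ = ["PredictiveSummary", "predictive_mean", "discrepancy"]


@dataclass(frozen=True)
class PredictiveSummary:
    """Posterior-predictive summary of a fitted visitation matrix.

    ``predictive_mean`` holds the per-pair predictive mean counts; because a
    replicate count is Poisson given network and parameters, its predictive
    standard deviation is approximated by ``sqrt(predictive_mean)``.
    ``between_draw_sd`` additionally reports the spread of the per-draw mean
    contributions across posterior draws.
    """

    predictive_mean: np.ndarray
    predictive_sd: np.ndarray
    between_draw_sd: np.ndarray
    residue: np.ndarray
    x2: float
    dof: int
    plant_labels: list[str]
    pollinator_labels: list[str]

    @property
    def x2_over_dof(self) -> float:
        return self.x2 / self.dof

    def to_report(self) -> dict:
        return {"x2": self.x2, "dof": self.dof, "x2_over_dof": self.x2_over_dof}


def _lambda_matrix(draws: ParameterDraws, data: VisitationMatrix):
    """Per-draw predictive mean contributions ``C s (1 + r Q)`` stacked over draws."""
    out = np.empty((len(draws), data.n_plants, data.n_pollinators))
    for k, params in enumerate(draws):
        q = edge_probability(params, data).probabilities
        base = params.C * np.outer(params.sigma, params.tau)
        # Q * mu(B=1) + (1 - Q) * mu(B=0) collapses to base * (1 + r Q)
        out[k] = base * (1.0 + params.r * q)
    return out


def predictive_mean(draws: ParameterDraws, data: VisitationMatrix) -> PredictiveSummary:
    """Predictive mean matrix, residue, and chi-squared discrepancy for the data."""
    if len(draws) < 1:
        raise ValueError("need at least one draw")
    contrib = _lambda_matrix(draws, data)
    lam = contrib.mean(axis=0)
    between = contrib.std(axis=0, ddof=1) if len(draws) > 1 else np.zeros_like(lam)
    residue = data.counts - lam
    dof = data.n_plants * data.n_pollinators
    summary = PredictiveSummary(
        predictive_mean=lam,
        predictive_sd=np.sqrt(lam),
        between_draw_sd=between,
        residue=residue,
        x2=0.0,
        dof=dof,
        plant_labels=data.plant_labels,
        pollinator_labels=data.pollinator_labels,
    )
    x2 = discrepancy(data, summary)
    object.__setattr__(summary, "x2", x2)
    return summary


def discrepancy(data: VisitationMatrix, summary: PredictiveSummary) -> float:
    """Chi-squared discrepancy ``sum_ij (M_ij - lambda_ij)^2 / lambda_ij``.

    Entries where both the count and the predictive mean are zero contribute
    nothing; a zero predictive mean facing a positive count makes the
    discrepancy infinite (with a warning).
    """
    m = data.counts
    lam = summary.predictive_mean
    if m.shape != lam.shape:
        raise ValueError("data and predictive mean shapes differ")
    zero = lam == 0
    if (zero & (m > 0)).any():
        warnings.warn(
            "zero predictive mean with positive count: infinite discrepancy",
            stacklevel=2,
        )
        return float("inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(zero, 0.0, (m - lam) ** 2 / np.where(zero, 1.0, lam))
    return float(terms.sum())
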