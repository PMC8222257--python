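"""End-to-end fit orchestration: load, sample, diagnose, summarize, write."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, metrics
from .assessment import predictive_mean
from .inference import (
    check_convergence,
    posterior_edge_matrix,
    sample_parameters,
    SamplerConfig,
)
from .model import PriorConfig, VisitationMatrix

logger = logging.getLogger("pollinet")

__all__ = ["RunConfig", "run_fit", "ConvergenceError"]

_METRICS = {"connectance": metrics.connectance, "nodf": metrics.nodf}


class ConvergenceError(RuntimeError):
    """Raised when chains remain trapped after exhausting the re-run budget."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a fit: inputs, priors, sampler, outputs."""

    input_paths: list[str]
    output_dir: str
    input_format: str = "labeled_csv"
    prior: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    seed: int = 0
    metric_names: list[str] = field(default_factory=lambda: ["connectance", "nodf"])
    trapped_threshold: float = 5.0
    max_restarts: int = 1

    def __post_init__(self) -> None:
        if not self.input_paths:
            raise ValueError("at least one input path is required")
        unknown = set(self.metric_names) - set(_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if self.max_restarts < 0:
            raise ValueError("max_restarts must be >= 0")

    def to_manifest(self) -> dict:
        return {
            "input_paths": list(self.input_paths),
            "input_format": self.input_format,
            "output_dir": str(self.output_dir),
            "prior": {"lambda_r": self.prior.lambda_r, "c_upper": self.prior.c_upper},
            "sampler": {
                "chains": self.sampler.chains,
                "warmup": self.sampler.warmup,
                "draws": self.sampler.draws,
                "target_accept": self.sampler.target_accept,
                "max_leapfrog": self.sampler.max_leapfrog,
            },
            "seed": self.seed,
            "metrics": list(self.metric_names),
            "trapped_threshold": self.trapped_threshold,
            "max_restarts": self.max_restarts,
            "pollinet_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }


def _load_input(config: RunConfig) -> VisitationMatrix:
    mats = [io.load_visitation_matrix(p, format=config.input_format) for p in config.input_paths]
    return mats[0] if len(mats) == 1 else metrics.aggregate(mats)


def run_fit(config: RunConfig) -> dict:
    """Execute the full pipeline and write the artifact bundle.

    Stages: load (aggregating multiple inputs) -> sample -> convergence check
    (with restarts on trapped chains) -> edge probabilities -> posterior
    predictive summary -> requested metric distributions -> manifest.
    Returns a dict of the in-memory artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = _load_input(config)
    logger.info(
        "loaded %d x %d matrix with %d observations",
        data.n_plants,
        data.n_pollinators,
        data.total,
    )

    seed = config.seed
    draws = report = None
    for attempt in range(config.max_restarts + 1):
        logger.info("sampling with seed %d (attempt %d)", seed, attempt + 1)
        draws = sample_parameters(data, prior=config.prior, config=config.sampler, seed=seed)
        report = check_convergence(draws, threshold=config.trapped_threshold)
        logger.info("%s", report.summary())
        if not report.trapped:
            break
        logger.warning("trapped chains %s; re-running", report.trapped_chains)
        seed += 104729  # deterministic restart offset
    if report.trapped:
        raise ConvergenceError(
            f"chains {report.trapped_chains} remained trapped after "
            f"{config.max_restarts + 1} attempts"
        )

    edge_probs = posterior_edge_matrix(draws, data)
    summary = predictive_mean(draws, data)

    metric_dists = {}
    for k, name in enumerate(config.metric_names):
        metric_dists[name] = metrics.posterior_metric(
            _METRICS[name], draws, data, seed=config.seed + 7919 * (k + 1)
        )

    io.write_visitation_matrix(data, out / "data.csv")
    io.write_draws(draws, out / "draws.csv")
    io.write_edge_probabilities(edge_probs, out / "edge_probabilities.csv")
    pd.DataFrame(
        summary.predictive_mean, index=data.plant_labels, columns=data.pollinator_labels
    ).to_csv(out / "predictive_mean.csv")
    pd.DataFrame(
        summary.residue, index=data.plant_labels, columns=data.pollinator_labels
    ).to_csv(out / "residue.csv")
    io.write_json(summary.to_report(), out / "predictive_summary.json")
    io.write_json(
        {name: dist.to_report() for name, dist in metric_dists.items()},
        out / "metrics.json",
    )
    for name, dist in metric_dists.items():
        pd.Series(dist.samples, name=name).to_csv(out / f"metric_{name}.csv", index=False)
    manifest = config.to_manifest()
    manifest["effective_seed"] = seed
    manifest["posterior_means"] = {
        "C": float(draws.C.mean()),
        "r": float(draws.r.mean()),
        "rho": float(draws.rho.mean()),
    }
    manifest["convergence"] = {
        "rhat": report.rhat,
        "trapped": report.trapped,
        "chain_mean_log_posterior": report.chain_mean_log_posterior,
    }
    io.write_json(manifest, out / "manifest.json")

    return {
        "data": data,
        "draws": draws,
        "edge_probabilities": edge_probs,
        "predictive_summary": summary,
        "metrics": metric_dists,
        "convergence": report,
        "manifest": manifest,
    }
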