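"""Readers and writers for visitation matrices, draw archives, and reports.

The labeled-CSV dialect puts pollinator labels on the first row and plant
labels in the first column, with integer counts in the cells.  The ``weblife``
dialect accepts the Web of Life matrix export, which uses the same layout but
may encode counts as floats and occasionally pads with empty rows or columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import EdgeProbabilityMatrix, ParameterDraws, SamplerConfig
from .model import VisitationMatrix

__all__ = [
    "load_visitation_matrix",
    "write_visitation_matrix",
    "write_edge_probabilities",
    "load_edge_probabilities",
    "write_draws",
    "load_draws",
    "write_json",
]


def _frame_to_matrix(df: pd.DataFrame, path) -> VisitationMatrix:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate plant labels {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate pollinator labels {dupes}")
    counts = np.empty(df.shape, dtype=np.int64)
    for i, (row_label, row) in enumerate(df.iterrows()):
        for j, (col_label, cell) in enumerate(row.items()):
            if pd.isna(cell):
                raise ValueError(
                    f"{path}: missing cell at plant {row_label!r}, pollinator {col_label!r}"
                )
            value = float(cell)
            if value < 0 or value != int(value):
                raise ValueError(
                    f"{path}: cell at plant {row_label!r}, pollinator {col_label!r} "
                    f"is not a non-negative integer ({cell!r})"
                )
            counts[i, j] = int(value)
    return VisitationMatrix(
        counts=counts,
        plant_labels=[str(x) for x in df.index],
        pollinator_labels=[str(x) for x in df.columns],
    )


def load_visitation_matrix(path, format: str = "labeled_csv") -> VisitationMatrix:
    """Read a visitation matrix in the labeled-CSV or Web of Life layout."""
    path = Path(path)
    if format == "labeled_csv":
        df = pd.read_csv(path, index_col=0)
    elif format == "weblife":
        df = pd.read_csv(path, index_col=0)
        df = df.dropna(axis=0, how="all").dropna(axis=1, how="all")
        df = df.loc[:, ~df.columns.str.startswith("Unnamed")]
    else:
        raise ValueError(f"unknown format {format!r}")
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError(f"{path}: empty matrix")
    return _frame_to_matrix(df, path)


def write_visitation_matrix(data: VisitationMatrix, path) -> None:
    df = pd.DataFrame(
        data.counts, index=data.plant_labels, columns=data.pollinator_labels
    )
    df.to_csv(path)


def write_edge_probabilities(edge_probs: EdgeProbabilityMatrix, path) -> None:
    edge_probs.to_dataframe().to_csv(path)


def load_edge_probabilities(path, n_theta: int = 1) -> EdgeProbabilityMatrix:
    df = pd.read_csv(path, index_col=0)
    return EdgeProbabilityMatrix(
        probabilities=df.to_numpy(dtype=float),
        plant_labels=[str(x) for x in df.index],
        pollinator_labels=[str(x) for x in df.columns],
        n_theta=n_theta,
    )


def write_draws(draws: ParameterDraws, path) -> None:
    """Tabular draw archive: one row per draw with chain provenance."""
    draws.to_dataframe().to_csv(path, index=False)


def load_draws(path, config: SamplerConfig | None = None) -> ParameterDraws:
    return ParameterDraws.from_dataframe(pd.read_csv(path), config=config)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
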