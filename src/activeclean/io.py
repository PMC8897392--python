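"""File I/O: label tables, feature matrices, configs, trajectories, results.

Label tables are CSV with header ``sample_id, count_0..count_{C-1}`` and
optionally ``true_0..true_{C-1}`` (one row per sample, counts integer,
distributions decimal).  Trajectories are TSV; run summaries are JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .label_model import NoisyDataset
from .simulation import CleaningResult, Trajectory

__all__ = [
    "read_label_table",
    "write_label_table",
    "read_features",
    "write_features",
    "read_config",
    "write_trajectory",
    "write_result",
]


class SchemaError(ValueError):
    """Malformed table: message carries the offending column or row number."""


def write_label_table(dataset: NoisyDataset, path) -> None:
    """Write a dataset's counts (and true distributions when present) as CSV."""
    C = dataset.n_categories
    data = {"sample_id": dataset.ids}
    for c in range(C):
        data[f"count_{c}"] = dataset.counts[:, c]
    if dataset.true_dists is not None:
        for c in range(C):
            data[f"true_{c}"] = dataset.true_dists[:, c]
    pd.DataFrame(data).to_csv(path, index=False)


def read_label_table(path) -> NoisyDataset:
    """Read a label-table CSV back into a dataset (lossless round-trip).

    Validates the header shape, integer counts, and that any distribution row
    sums to 1 within 1e-6; errors name the offending row.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SchemaError("missing 'sample_id' column")
    count_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"count_\d+", c)),
        key=lambda c: int(c.split("_")[1]),
    )
    if not count_cols:
        raise SchemaError("no count_<c> columns found")
    C = len(count_cols)
    expected = [f"count_{c}" for c in range(C)]
    if count_cols != expected:
        raise SchemaError(f"count columns must be contiguous count_0..count_{C - 1}")
    true_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"true_\d+", c)),
        key=lambda c: int(c.split("_")[1]),
    )
    if true_cols and true_cols != [f"true_{c}" for c in range(C)]:
        raise SchemaError("true_<c> columns must match the count columns")

    counts = df[expected].to_numpy()
    if np.any(counts != counts.astype(np.int64)):
        bad = int(np.argwhere(counts != counts.astype(np.int64))[0, 0])
        raise SchemaError(f"non-integer count at row {bad + 2}")  # 1-based + header
    counts = counts.astype(np.int64)

    true_dists = None
    if true_cols:
        true_dists = df[true_cols].to_numpy(dtype=float)
        sums = true_dists.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if bad.size:
            raise SchemaError(f"distribution does not sum to 1 at row {bad[0] + 2}")
    return NoisyDataset(ids=list(df["sample_id"]), counts=counts, true_dists=true_dists)


def write_features(ids, features: np.ndarray, path) -> None:
    """Write a per-sample feature/embedding matrix as CSV (row per sample)."""
    features = np.asarray(features, dtype=float)
    data = {"sample_id": list(ids)}
    for j in range(features.shape[1]):
        data[f"f_{j}"] = features[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_features(path) -> tuple[list, np.ndarray]:
    """Read a feature CSV; returns (ids, N x d matrix)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SchemaError("missing 'sample_id' column")
    cols = [c for c in df.columns if c != "sample_id"]
    return list(df["sample_id"]), df[cols].to_numpy(dtype=float)


def read_config(path) -> dict:
    """Load a JSON or YAML run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Dump a trajectory as TSV: annotations_consumed, label_accuracy, noise_rate."""
    df = pd.DataFrame({
        "annotations_consumed": trajectory.annotations,
        "label_accuracy": trajectory.accuracy,
        "noise_rate": trajectory.noise_rate,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_result(result: CleaningResult, path, config_echo: dict | None = None) -> None:
    """Dump a run summary as JSON: AUC, final accuracy, consumption, config echo."""
    payload = {
        "auc": None if np.isnan(result.auc) else result.auc,
        "final_accuracy": result.final_accuracy,
        "consumed": result.consumed,
        "budget": result.ledger.budget,
        "finetune_events": result.finetune_events,
        "config": config_echo or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
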