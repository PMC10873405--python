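"""Plain-text I/O for datasets, rankings and optimizer traces.

Matrices travel as TSV with a header row of feature IDs and a first
column of sample IDs — the layout typical of expression matrices — so
synthetic and user-supplied data share one format.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .simulate import SimulatedDataset, SimulationConfig

__all__ = [
    "write_dataset",
    "read_matrix",
    "read_phenotype",
    "write_selection_result",
    "write_trace",
]


def write_dataset(ds: SimulatedDataset, prefix: str) -> None:
    """Write X/y/causal/config files under a path prefix."""
    prefix = str(prefix)
    n, p = ds.X.shape
    samples = [f"S{i}" for i in range(n)]
    pd.DataFrame(
        ds.X, index=samples, columns=[f"F{j}" for j in range(p)]
    ).to_csv(f"{prefix}_X.tsv", sep="\t", index_label="sample")
    pd.DataFrame({"sample": samples, "y": ds.y}).to_csv(
        f"{prefix}_y.tsv", sep="\t", index=False
    )
    np.savetxt(f"{prefix}_causal.txt", ds.causal_indices, fmt="%d")
    with open(f"{prefix}_config.json", "w") as fh:
        json.dump(dataclasses.asdict(ds.config), fh, indent=2)


def read_matrix(path: str) -> Tuple[np.ndarray, list, list]:
    """Read a samples x features TSV; returns (matrix, sample IDs, feature IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def read_phenotype(path: str, column: str | None = None) -> Tuple[np.ndarray, list]:
    """Read a (sample ID, value) phenotype table; returns (values, sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = column or df.columns[0]
    return df[col].to_numpy(dtype=float), list(df.index)


def write_selection_result(result, path: str, trace_path: str | None = None) -> None:
    payload = {
        "method": result.method,
        "tuner": result.tuner,
        "ranked_indices": [int(i) for i in result.ranked_indices],
        "scores": [float(s) for s in result.scores],
        "hyperparams": result.hyperparams,
        "n_requested": result.n_requested,
    }
    if result.trace is not None and trace_path:
        write_trace(result.trace, trace_path)
        payload["trace"] = str(trace_path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_trace(trace, path_prefix: str) -> None:
    """Export a BO trace as CSV (history) plus JSON (summary)."""
    prefix = Path(path_prefix)
    trace.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(trace.summary(), fh, indent=2)
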