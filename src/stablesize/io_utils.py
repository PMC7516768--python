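"""Plain-text IO: TSV samples/histograms, JSON results, run manifests."""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_sizes_tsv",
    "write_sizes_tsv",
    "write_size_histogram_tsv",
    "write_trajectory_tsv",
    "write_edge_list",
    "write_json",
    "RunManifest",
]


def read_sizes_tsv(path) -> np.ndarray:
    """Read a size sample: one-column (sizes) or two-column (size, count).

    A header line is permitted; two-column input is expanded to a flat
    sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy()
    if df.shape[1] == 2:
        sizes = df.iloc[:, 0].to_numpy()
        counts = df.iloc[:, 1].to_numpy(dtype=np.int64)
        return np.repeat(sizes, counts)
    raise ValueError("expected a one- or two-column TSV of sizes or size/count")


def write_sizes_tsv(path, samples) -> None:
    """Write a flat sample as one 'size' column."""
    pd.DataFrame({"size": np.asarray(samples)}).to_csv(path, sep="\t", index=False)


def write_size_histogram_tsv(path, samples) -> None:
    """Write a (size, count) table of the sample."""
    values, counts = np.unique(np.asarray(samples), return_counts=True)
    pd.DataFrame({"size": values, "count": counts}).to_csv(path, sep="\t", index=False)


def write_trajectory_tsv(path, trajectory, columns=("t", "N_t", "q_t")) -> None:
    pd.DataFrame(np.asarray(trajectory), columns=list(columns)).to_csv(
        path, sep="\t", index=False
    )


def write_edge_list(path, edges) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u} {v}\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclasses.dataclass
class RunManifest:
    """Record of one CLI invocation sufficient to reproduce its outputs."""

    command: str
    config: dict
    seed: int | None
    version: str
    outputs: list
    wall_time_s: float = 0.0
    _t0: float = dataclasses.field(default_factory=time.monotonic, repr=False)

    def finish(self, path) -> None:
        self.wall_time_s = round(time.monotonic() - self._t0, 3)
        payload = {
            "command": self.command,
            "config": _jsonable(self.config),
            "seed": self.seed,
            "version": self.version,
            "outputs": [str(p) for p in self.outputs],
            "wall_time_s": self.wall_time_s,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
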