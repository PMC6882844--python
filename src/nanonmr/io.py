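"""Reading and writing traces, datasets and raw detection streams.

Two on-disk forms are supported:

* columnar CSV with header ``trace_id,t,bit`` (one row per measurement,
  ``t`` in seconds), convenient for inspection and interoperability;
* a compact form — one trace per line as a contiguous 0/1 string — with a
  JSON sidecar carrying ``dt``, labels and the generating parameters.

Raw streams are plain text: one 0/1 token per line, or one or more
contiguous 0/1 strings (whitespace-separated chunks are concatenated).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import Dataset, Trace

__all__ = [
    "write_dataset_csv",
    "read_dataset_csv",
    "write_dataset_compact",
    "read_dataset_compact",
    "read_raw_stream",
]

PathLike = Union[str, Path]


def write_dataset_csv(dataset: Dataset, path: PathLike) -> None:
    frames = []
    for i, tr in enumerate(dataset):
        frames.append(pd.DataFrame({
            "trace_id": i,
            "t": tr.times,
            "bit": tr.bits,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dataset_csv(path: PathLike,
                     labels: Optional[dict] = None) -> Dataset:
    df = pd.read_csv(path)
    required = {"trace_id", "t", "bit"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("t")
        lab = labels.get(tid) if labels else None
        traces.append(Trace(grp["bit"].to_numpy(), grp["t"].to_numpy(), lab))
    return Dataset(traces)


def write_dataset_compact(dataset: Dataset, path: PathLike,
                          sidecar: Optional[PathLike] = None) -> None:
    """One 0/1 string per line plus a JSON sidecar (default: path + '.json')
    with dt, trace labels and the dataset metadata."""
    path = Path(path)
    with path.open("w") as fh:
        for tr in dataset:
            fh.write("".join(map(str, tr.bits.tolist())) + "\n")
    side = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    labels = [tr.label for tr in dataset]

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.random.SeedSequence):
            return obj.entropy
        return obj

    with side.open("w") as fh:
        json.dump({
            "dt": float(dataset.times[1] - dataset.times[0])
            if len(dataset.times) > 1 else float(dataset.times[0]),
            "labels": labels,
            "metadata": _clean(dataset.metadata),
        }, fh, indent=1, default=str)


def read_dataset_compact(path: PathLike,
                         sidecar: Optional[PathLike] = None) -> Dataset:
    path = Path(path)
    side = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    with side.open() as fh:
        info = json.load(fh)
    dt = float(info["dt"])
    labels = info.get("labels")
    traces = []
    with path.open() as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            bits = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            times = dt * np.arange(1, len(bits) + 1)
            lab = labels[i] if labels else None
            traces.append(Trace(bits, times, lab))
    return Dataset(traces, info.get("metadata") or {})


def read_raw_stream(path: PathLike) -> np.ndarray:
    """Read a raw 0/1 detection stream from plain text."""
    tokens = Path(path).read_text().split()
    if not tokens:
        raise ValueError(f"{path} contains no 0/1 tokens")
    chunks = []
    for tok in tokens:
        if set(tok) - {"0", "1"}:
            raise ValueError(f"non-binary token {tok!r} in {path}")
        chunks.append(np.frombuffer(tok.encode(), dtype=np.uint8) - ord("0"))
    return np.concatenate(chunks)
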