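"""File formats: trace CSV + JSON sidecar, event tables, summaries, configs.

Traces travel as two-column CSV with the exact header ``time_s,v_mv`` and a
uniform, strictly increasing time grid; per-cell metadata lives in a JSON
sidecar (``<trace>.meta.json``) with keys cell_id, sex, condition,
capacitance_pf, days_in_culture, fs_hz, seed.  Event tables and per-cell
summaries are plain CSV.  Round trips are loss-free to well below 1e-9.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .events import CellSummary, Event, EventTable, Trace
from .synthgen import TruthEvent

__all__ = [
    "write_trace", "read_trace",
    "write_events", "read_events",
    "write_truth", "read_truth",
    "write_summaries", "read_summaries",
    "read_config", "write_provenance",
]

TRACE_HEADER = "time_s,v_mv"
_SIDEBAR_SUFFIX = ".meta.json"

METADATA_KEYS = ("cell_id", "sex", "condition", "capacitance_pf",
                 "days_in_culture", "fs_hz", "seed")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + _SIDEBAR_SUFFIX)


def write_trace(path: str | Path, trace: Trace) -> None:
    """Write a trace as ``time_s,v_mv`` CSV plus a JSON metadata sidecar."""
    path = Path(path)
    t = trace.t_s
    with open(path, "w") as fh:
        fh.write(TRACE_HEADER + "\n")
        for ti, vi in zip(t, trace.v_mv):
            fh.write(f"{ti:.9f},{vi:.9f}\n")
    meta = {k: trace.metadata[k] for k in METADATA_KEYS
            if trace.metadata.get(k) is not None}
    meta["fs_hz"] = trace.fs_hz
    meta.update({k: v for k, v in trace.metadata.items()
                 if k not in meta and _json_safe(v)})
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _json_safe(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None)))


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV (strict header and uniform-grid checks) + sidecar."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if header != TRACE_HEADER:
        raise ValueError(f"{path}: expected header {TRACE_HEADER!r}, "
                         f"got {header!r}")
    arr = pd.read_csv(path).to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if dt.min() <= 0 or np.abs(dt - dt[0]).max() > 1e-7:
        # diff i spans data rows i+1, i+2; +1 more for the header line
        bad = int(np.argmax(np.abs(dt - dt[0]))) + 3
        raise ValueError(f"{path}: non-uniform time grid at line {bad}")
    metadata = {}
    side = _sidecar_path(path)
    if side.exists():
        with open(side) as fh:
            metadata = json.load(fh)
    fs = float(metadata.get("fs_hz") or 1.0 / dt[0])
    return Trace(v_mv=v, fs_hz=fs, t0_s=float(t[0]), metadata=metadata)


def write_events(path: str | Path, table: EventTable) -> None:
    df = table.to_dataframe()
    df.insert(0, "baseline_mv", table.baseline_mv)
    df.insert(0, "recording_duration_s", table.recording_duration_s)
    df.to_csv(path, index=False, float_format="%.9f")


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "peak_v_mv", "amplitude_mv",
                "n_spikelets", "class"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    events = [Event(start_s=r["start_s"], end_s=r["end_s"],
                    peak_v_mv=r["peak_v_mv"], amplitude_mv=r["amplitude_mv"],
                    n_spikelets=int(r["n_spikelets"]), klass=str(r["class"]))
              for r in df.to_dict("records")]
    dur = float(df["recording_duration_s"].iloc[0]) if len(df) else 0.0
    base = float(df["baseline_mv"].iloc[0]) if len(df) else float("nan")
    return EventTable(events=events, recording_duration_s=dur,
                      baseline_mv=base)


def write_truth(path: str | Path, truth: list[TruthEvent]) -> None:
    pd.DataFrame(truth, columns=["start_s", "end_s", "class", "n_spikelets"]) \
        .to_csv(path, index=False, float_format="%.9f")


def read_truth(path: str | Path) -> list[TruthEvent]:
    df = pd.read_csv(path)
    return [TruthEvent(r["start_s"], r["end_s"], str(r["class"]),
                       int(r["n_spikelets"]))
            for r in df.to_dict("records")]


def write_summaries(path: str | Path, summaries: list[CellSummary]) -> None:
    pd.DataFrame([s.as_dict() for s in summaries]) \
        .to_csv(path, index=False, float_format="%.9f")


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    return cfg


def write_provenance(path: str | Path, config: dict, seed: int | None) -> None:
    """Record versions, a config hash, and the seed for a pipeline run."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)
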