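"""Delimited-text I/O for traces, results, event logs and manifests.

Trace files are long-format CSV with a required header and columns
``cell_id,time_s,length_um`` plus optional ``group`` and ``batch``;
UTF-8, "." decimal, no locale-dependent parsing.  Malformed data rows
are rejected individually with their line numbers rather than failing
the whole file.  Result files round-trip at full float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mechanics import LengthTrace

__all__ = [
    "TraceReadResult",
    "read_traces",
    "write_traces",
    "write_results",
    "read_results",
    "write_event_log",
    "write_manifest",
]

REQUIRED_COLUMNS = ("cell_id", "time_s", "length_um")
OPTIONAL_COLUMNS = ("group", "batch")


@dataclass
class TraceReadResult:
    """Parsed traces plus an itemised list of rejected rows."""

    traces: list[LengthTrace]
    rejected_rows: list[tuple[int, str]]  # (1-based file line, reason)


def read_traces(path) -> TraceReadResult:
    """Read a long-format trace CSV into :class:`LengthTrace` objects.

    Raises on a missing file, an empty file or missing required columns;
    individual rows with non-numeric values are skipped and reported in
    ``rejected_rows`` with their file line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")

    time = pd.to_numeric(df["time_s"], errors="coerce")
    length = pd.to_numeric(df["length_um"], errors="coerce")
    bad = time.isna() | length.isna()
    rejected = [
        (int(i) + 2, f"non-numeric time_s/length_um: {df.time_s[i]!r}/{df.length_um[i]!r}")
        for i in df.index[bad]
    ]  # +2: 1-based lines plus header
    good = df[~bad].assign(time_s=time[~bad], length_um=length[~bad])

    traces = []
    for cid, sub in good.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_s")
        group = sub["group"].iloc[0] if "group" in sub.columns else None
        batch = sub["batch"].iloc[0] if "batch" in sub.columns else None
        traces.append(
            LengthTrace(
                cell_id=str(cid),
                times=sub["time_s"].to_numpy(dtype=float),
                lengths=sub["length_um"].to_numpy(dtype=float),
                group=group or None,
                batch_id=batch or None,
            )
        )
    return TraceReadResult(traces=traces, rejected_rows=rejected)


def write_traces(path, traces) -> None:
    """Write traces to long-format CSV (full precision, lossless)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "time_s": tr.times,
                    "length_um": tr.lengths,
                    "group": tr.group or "",
                    "batch": tr.batch_id or "",
                }
            )
        )
    if not frames:
        raise ValueError("no traces to write")
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format=None)


def write_results(path, results: pd.DataFrame) -> None:
    """Write a per-cell results table (full float precision)."""
    results.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def write_event_log(path, log) -> None:
    """Write an :class:`~depstretch.simulator.EventLog` as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        header = {
            "seed": log.seed,
            "n_ports": log.n_ports,
            "controller": {
                k: (v if not isinstance(v, np.generic) else v.item())
                for k, v in vars(log.controller).items()
            },
        }
        fh.write(json.dumps({"run": header}) + "\n")
        for cyc in log.cycles:
            fh.write(json.dumps(cyc.to_json_dict()) + "\n")


def write_manifest(path, *, config_hash: str, seed: int, outputs: list[str]) -> None:
    """Write a run manifest: config hash, seed, package version, outputs."""
    from . import __version__

    manifest = {
        "package": "depstretch",
        "version": __version__,
        "config_sha256": config_hash,
        "seed": seed,
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
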