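"""Readers and writers for the pipeline's plain-text interchange formats.

Long-format trace tables (TSV/CSV, delimiter inferred), flow-cytometry
snapshot tables, calibration tables, BED3+ interval files and the wide
synchronized matrices all round-trip through here.  Every writer prefixes
a deterministic provenance comment (package version and seed, no
timestamp) so same-seed outputs stay byte-identical.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import TRACE_COLUMNS, CalibrationSet, SynchronizedTraceSet, TraceSet, validate_snapshot

__all__ = [
    "read_trace_table",
    "write_trace_table",
    "read_snapshot",
    "write_snapshot",
    "read_calibration",
    "write_calibration",
    "read_intervals",
    "write_synchronized",
    "write_json",
    "provenance",
]

logger = logging.getLogger("flucdyn")


def provenance(seed: int | None = None) -> str:
    tail = "" if seed is None else f" seed={seed}"
    return f"# flucdyn v{__version__}{tail}"


def _sep_for(path: Path, text: str) -> str:
    if path.suffix.lower() == ".tsv":
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    try:
        return csv.Sniffer().sniff(text, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if not line.startswith("#"):
                first = line
                break
    sep = _sep_for(path, first)
    return pd.read_csv(path, sep=sep, comment="#")


def read_trace_table(path: str | Path) -> TraceSet:
    """Read a long-format trace table (TSV/CSV with a one-line header).

    Required columns: cell_id, frame, time_h, channel, intensity,
    background, cycle_id, division_flag.  An optional ``unit`` column
    carries per-channel unit labels.
    """
    df = _read_table(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column: {missing[0]}")
    units = {}
    if "unit" in df.columns:
        units = {
            ch: sub["unit"].iloc[0] for ch, sub in df.groupby("channel", sort=False)
        }
        df = df.drop(columns=["unit"])
    df["cell_id"] = df["cell_id"].astype(str)
    traces = TraceSet(df.reset_index(drop=True), units=units)
    logger.info("read %d trace rows from %s", len(df), path)
    return traces


def write_trace_table(traces: TraceSet, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    df = traces.data.copy()
    if traces.units:
        df["unit"] = df["channel"].map(lambda ch: traces.unit_of(ch))
    with open(path, "w") as fh:
        fh.write(provenance(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_snapshot(path: str | Path) -> pd.DataFrame:
    return validate_snapshot(_read_table(path))


def write_snapshot(snapshot: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance(seed) + "\n")
        snapshot.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_calibration(path: str | Path, phi_f: float) -> CalibrationSet:
    return CalibrationSet(_read_table(path), phi_f=phi_f)


def write_calibration(cal: CalibrationSet, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance(seed) + "\n")
        cal.data.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into 0-based half-open intervals, sorted per chromosome."""
    rows = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric coordinates") from None
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def write_synchronized(sync: SynchronizedTraceSet, path: str | Path, seed: int | None = None) -> None:
    """Write the wide synchronized matrix plus a JSON metadata sidecar."""
    path = Path(path)
    wide = sync.values.copy()
    wide.columns = [f"{c:.6g}" for c in wide.columns]
    with open(path, "w") as fh:
        fh.write(provenance(seed) + "\n")
        wide.to_csv(fh, sep="\t", lineterminator="\n")
    meta = {
        "channel": sync.channel,
        "unit": sync.unit,
        "grid_size": sync.grid_size,
        "n_excluded": sync.n_excluded,
        "durations_h": {
            f"{c}|{cyc}": float(v) for (c, cyc), v in sync.durations_h.items()
        },
        "start_time_h": {
            f"{c}|{cyc}": float(v) for (c, cyc), v in sync.start_time_h.items()
        },
    }
    write_json(meta, path.with_suffix(path.suffix + ".meta.json"), seed=seed)


def write_json(payload: dict, path: str | Path, seed: int | None = None) -> None:
    payload = dict(payload)
    payload["provenance"] = {"package": "flucdyn", "version": __version__, "seed": seed}

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
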