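"""In-memory containers shared across the pipeline.

The universal interchange object is the :class:`TraceSet`: a long-format
table with one row per (cell, frame, channel) holding raw intensity, the
locally measured background, cell-cycle annotations and division flags --
the shape a manual-tracking export naturally takes.  Synchronized data
lives in a :class:`SynchronizedTraceSet`, a wide matrix over a shared
cell-cycle-progression grid theta in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRACE_COLUMNS",
    "TraceSet",
    "SynchronizedTraceSet",
    "CalibrationSet",
    "SNAPSHOT_COLUMNS",
    "validate_snapshot",
]

#: Required columns of the long-format trace table.
TRACE_COLUMNS = [
    "cell_id",
    "frame",
    "time_h",
    "channel",
    "intensity",
    "background",
    "cycle_id",
    "division_flag",
]

#: Required columns of a flow-cytometry-like snapshot table.
SNAPSHOT_COLUMNS = ["sox2_level", "oct4_level", "dna_content"]


@dataclass
class TraceSet:
    """Long-format single-cell trace table with per-channel unit labels.

    ``data`` holds one row per (cell_id, frame, channel); ``units`` maps a
    channel name to its intensity unit ("au" or "molecules").
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> "TraceSet":
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing column: {missing[0]}")
        if len(self.data):
            if not np.isfinite(self.data["intensity"].to_numpy(float)).all():
                raise ValueError("raw intensity contains non-finite values")
            for (cell, channel), sub in self.data.groupby(
                ["cell_id", "channel"], sort=False
            ):
                t = sub["time_h"].to_numpy(float)
                if np.any(np.diff(t) <= 0):
                    raise ValueError(
                        f"time_h not strictly increasing for cell {cell!r}, "
                        f"channel {channel!r}"
                    )
        return self

    def channels(self) -> list[str]:
        return list(pd.unique(self.data["channel"]))

    def unit_of(self, channel: str) -> str:
        return self.units.get(channel, "au")

    def select_channel(self, channel: str) -> pd.DataFrame:
        sub = self.data[self.data["channel"] == channel]
        if sub.empty:
            raise ValueError(f"channel {channel!r} not present in TraceSet")
        return sub

    def copy(self) -> "TraceSet":
        return TraceSet(self.data.copy(), dict(self.units))

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SynchronizedTraceSet:
    """Per-cycle traces resampled onto a shared progression grid.

    ``values`` is indexed by (cell_id, cycle_id) with one column per
    gridpoint theta_k = k / (G - 1); ``durations_h`` and ``start_time_h``
    carry each cycle's wall-clock duration and absolute start time.
    """

    values: pd.DataFrame
    durations_h: pd.Series
    start_time_h: pd.Series
    channel: str
    unit: str = "au"
    n_excluded: int = 0

    @property
    def theta(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def grid_size(self) -> int:
        return self.values.shape[1]

    def cell_ids(self) -> list:
        return list(self.values.index.get_level_values("cell_id").unique())

    def per_cell_matrix(self, n_cycles: int = 1) -> tuple[pd.DataFrame, int]:
        """Concatenate the first ``n_cycles`` cycles of each cell.

        Returns a cells x (n_cycles * G) matrix (columns: cumulative
        progression in cycle units) and the number of cells dropped for
        having fewer than ``n_cycles`` complete cycles (complete-case
        handling).
        """
        rows, index = [], []
        dropped = 0
        theta = self.theta
        for cell, sub in self.values.groupby(level="cell_id", sort=False):
            sub = sub.sort_index(level="cycle_id")
            if len(sub) < n_cycles:
                dropped += 1
                continue
            rows.append(np.concatenate([sub.iloc[k].to_numpy() for k in range(n_cycles)]))
            index.append(cell)
        if not rows:
            raise ValueError(f"no cell has {n_cycles} complete cycles")
        cols = np.concatenate([theta + k for k in range(n_cycles)])
        return pd.DataFrame(rows, index=pd.Index(index, name="cell_id"), columns=cols), dropped

    def copy(self) -> "SynchronizedTraceSet":
        return SynchronizedTraceSet(
            self.values.copy(),
            self.durations_h.copy(),
            self.start_time_h.copy(),
            self.channel,
            self.unit,
            self.n_excluded,
        )


@dataclass
class CalibrationSet:
    """Per-calibration-cell NLUC/FLUC intensity pairs plus the known
    FLUC detection constant ``phi_f`` (intensity units per molecule)."""

    data: pd.DataFrame  # columns: nluc_intensity, fluc_intensity
    phi_f: float

    def __post_init__(self) -> None:
        for col in ("nluc_intensity", "fluc_intensity"):
            if col not in self.data.columns:
                raise ValueError(f"missing column: {col}")
        if not (self.phi_f > 0):
            raise ValueError(f"phi_f must be > 0, got {self.phi_f!r}")

    def __len__(self) -> int:
        return len(self.data)


def validate_snapshot(snapshot: pd.DataFrame, require_levels: bool = True) -> pd.DataFrame:
    """Validate a snapshot (flow-cytometry-like) event table."""
    required = SNAPSHOT_COLUMNS if require_levels else ["dna_content"]
    missing = [c for c in required if c not in snapshot.columns]
    if missing:
        raise ValueError(f"missing column: {missing[0]}")
    dna = snapshot["dna_content"].to_numpy(float)
    if not (np.isfinite(dna).all() and (dna > 0).all()):
        raise ValueError("dna_content must be finite and > 0")
    for col in snapshot.columns:
        if col != "dna_content" and not np.isfinite(snapshot[col].to_numpy(float)).all():
            raise ValueError(f"column {col!r} contains non-finite values")
    return snapshot
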