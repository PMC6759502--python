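"""In-silico cell-cycle synchronization and nuclear-volume normalization.

Each complete cell cycle (a cycle whose last sample carries a division
flag) is mapped onto a normalized progression axis theta in [0, 1] by
linear interpolation of the time variable, giving every cell the same
grid regardless of its wall-clock cycle duration.  Molecule numbers are
converted to nuclear concentration with a linearly growing nuclear volume
V(theta) = v0 * (1 + theta) -- the unique growth law under which a protein
whose copy number doubles over the cycle keeps a constant concentration.
A population-trend detrender removes global acquisition drifts (e.g.
photobleaching-like intensity loss) by dividing each trace by the
first-frame-normalized population mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import SynchronizedTraceSet, TraceSet
from .datasets import MOLECULES_PER_NM_FL

__all__ = [
    "CellCycleSynchronizer",
    "PopulationDetrender",
    "synchronize",
    "nuclear_volume",
    "to_concentration",
    "detrend_population",
]


def nuclear_volume(theta, v0_fl: float):
    """Nuclear volume (fL) at cell-cycle progression theta: v0 * (1 + theta)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    if not (v0_fl > 0):
        raise ValueError("v0_fl must be > 0")
    out = v0_fl * (1.0 + theta)
    return float(out) if out.ndim == 0 else out


class CellCycleSynchronizer(BaseEstimator):
    """Resample complete cycles onto a shared progression grid.

    Parameters
    ----------
    grid_size : int
        Number of gridpoints G; theta_k = k / (G - 1).
    channel : str or None
        Channel to synchronize; None is allowed when the trace set has a
        single channel.

    Attributes
    ----------
    n_excluded_ : int
        Cycles dropped for missing a boundary or having < 2 samples.
    """

    def __init__(self, grid_size: int = 100, channel: str | None = None):
        self.grid_size = grid_size
        self.channel = channel

    def fit(self, traces: TraceSet, y=None) -> "CellCycleSynchronizer":
        return self

    def transform(self, traces: TraceSet) -> SynchronizedTraceSet:
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        channel = self.channel
        if channel is None:
            channels = traces.channels()
            if len(channels) != 1:
                raise ValueError(
                    f"trace set has channels {channels}; specify which to synchronize"
                )
            channel = channels[0]
        sub = traces.select_channel(channel)
        grid = np.linspace(0.0, 1.0, self.grid_size)

        rows, durations, starts, index = [], [], [], []
        n_excluded = 0
        for (cell, cycle), grp in sub.groupby(["cell_id", "cycle_id"], sort=False):
            grp = grp.sort_values("time_h")
            t = grp["time_h"].to_numpy(float)
            v = grp["intensity"].to_numpy(float)
            complete = len(grp) >= 2 and grp["division_flag"].iloc[-1] == 1
            if not complete:
                n_excluded += 1
                continue
            theta = (t - t[0]) / (t[-1] - t[0])
            rows.append(np.interp(grid, theta, v))
            durations.append(t[-1] - t[0])
            starts.append(t[0])
            index.append((cell, cycle))
        if not rows:
            raise ValueError("no complete cycles to synchronize")
        idx = pd.MultiIndex.from_tuples(index, names=["cell_id", "cycle_id"])
        self.n_excluded_ = n_excluded
        return SynchronizedTraceSet(
            values=pd.DataFrame(rows, index=idx, columns=grid),
            durations_h=pd.Series(durations, index=idx, name="duration_h"),
            start_time_h=pd.Series(starts, index=idx, name="start_time_h"),
            channel=channel,
            unit=traces.unit_of(channel),
            n_excluded=n_excluded,
        )


def synchronize(
    traces: TraceSet, grid_size: int = 100, channel: str | None = None
) -> SynchronizedTraceSet:
    """Resample each complete cycle onto theta_k = k/(G-1) by linear interpolation."""
    return CellCycleSynchronizer(grid_size=grid_size, channel=channel).transform(traces)


def to_concentration(sync: SynchronizedTraceSet, v0_fl: float) -> SynchronizedTraceSet:
    """Convert synchronized molecule numbers to nuclear concentration (nM).

    conc(theta) = N(theta) / (N_A * V(theta) * 1e-15 L) * 1e9 with the
    linear volume model V(theta) = v0 * (1 + theta).
    """
    if sync.unit != "molecules":
        raise ValueError(
            f"to_concentration requires values in molecules, got unit {sync.unit!r}"
        )
    volumes = nuclear_volume(sync.theta, v0_fl)
    out = sync.copy()
    out.values = sync.values / (volumes * MOLECULES_PER_NM_FL)
    out.unit = "nM"
    return out


class PopulationDetrender(BaseEstimator):
    """Remove a shared per-frame intensity trend from all traces.

    The trend is the population-mean intensity per frame normalized to its
    first-frame value; every trace is divided by it.  Frames with no cells
    get an interpolated trend value.
    """

    def __init__(self, channel: str | None = None):
        self.channel = channel

    def fit(self, traces: TraceSet, y=None) -> "PopulationDetrender":
        channel = self.channel
        if channel is None:
            channels = traces.channels()
            if len(channels) != 1:
                raise ValueError(
                    f"trace set has channels {channels}; specify which to detrend"
                )
            channel = channels[0]
        sub = traces.select_channel(channel)
        per_frame = sub.groupby("frame")["intensity"].mean()
        frames = np.arange(int(sub["frame"].min()), int(sub["frame"].max()) + 1)
        trend = pd.Series(np.nan, index=frames, dtype=float)
        trend.loc[per_frame.index] = per_frame.to_numpy()
        if np.isnan(trend.iloc[0]):
            raise ValueError("first frame has no cells; cannot anchor the trend")
        trend = trend.interpolate(method="linear", limit_direction="forward")
        trend = trend / trend.iloc[0]
        n_cells = sub["cell_id"].nunique()
        if n_cells < 2:
            warnings.warn(
                "detrending a single cell makes its own trace constant",
                stacklevel=2,
            )
        self.channel_ = channel
        self.trend_ = trend
        return self

    def transform(self, traces: TraceSet) -> TraceSet:
        if not hasattr(self, "trend_"):
            raise ValueError("PopulationDetrender is not fitted")
        out = traces.copy()
        mask = out.data["channel"] == self.channel_
        factors = self.trend_.reindex(out.data.loc[mask, "frame"]).to_numpy()
        if np.isnan(factors).any():
            raise ValueError("trace contains frames outside the fitted trend")
        out.data.loc[mask, "intensity"] = out.data.loc[mask, "intensity"].to_numpy() / factors
        out.data.loc[mask, "background"] = (
            out.data.loc[mask, "background"].to_numpy() / factors
        )
        return out

    def fit_transform(self, traces: TraceSet, y=None) -> TraceSet:
        return self.fit(traces).transform(traces)


def detrend_population(traces: TraceSet, channel: str | None = None) -> TraceSet:
    """Divide every trace by the first-frame-normalized population mean."""
    return PopulationDetrender(channel=channel).fit_transform(traces)
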