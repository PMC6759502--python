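"""Reporter-based fate classification and cycle-aligned group comparison.

A cell is called reporter-positive from the first moment its FLUC signal
exceeds a molecule threshold continuously for a minimum duration
(defaults: 500 molecules for at least 4 h).  Because the sampling
interval is coarser than the rule, run boundaries are located by linear
interpolation of the threshold-crossing times, and a run's duration is
measured between interpolated crossings.  Cell cycles are then labelled
along the lineage: the cycle containing the onset is ``turning_positive``,
the immediately preceding cycle ``before_positive``, later cycles
``positive``, everything else (and all cycles of never-positive cells)
``negative``.

``align_and_compare`` contrasts the SOX2 trajectories of committing and
non-committing cells on the synchronized grid over the three-cycle window
(before / turning / after); negative cells are aligned by absolute time so
that their window midpoints match the positive group's mean midpoint, and
a two-sided Welch test is run per gridpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import SynchronizedTraceSet, TraceSet

__all__ = [
    "FateLabels",
    "ReporterFateClassifier",
    "classify_reporter",
    "align_and_compare",
    "GroupComparison",
]

LABELS = ("negative", "before_positive", "turning_positive", "positive")


@dataclass
class FateLabels:
    """Per (cell_id, cycle_id) fate labels plus per-cell onset times."""

    labels: pd.DataFrame  # columns: cell_id, cycle_id, label
    onset_h: pd.Series  # per cell_id; NaN when never positive

    def of(self, cell_id, cycle_id) -> str:
        sub = self.labels
        hit = sub[(sub["cell_id"] == cell_id) & (sub["cycle_id"] == cycle_id)]
        if hit.empty:
            raise KeyError((cell_id, cycle_id))
        return hit["label"].iloc[0]


def _onset_time(t: np.ndarray, f: np.ndarray, threshold: float, min_hours: float):
    """Start time of the first interpolated super-threshold run >= min_hours.

    Runs are maximal stretches with f > threshold; a run starting (ending)
    inside the record has its boundary placed at the linearly interpolated
    threshold crossing.  Returns None when no qualifying run exists.
    """
    above = f > threshold
    if not above.any():
        return None
    n = len(f)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        # interpolated run boundaries
        if i == 0:
            start = t[0]
        else:
            frac = (threshold - f[i - 1]) / (f[i] - f[i - 1])
            start = t[i - 1] + frac * (t[i] - t[i - 1])
        if j == n - 1:
            end = t[-1]
        else:
            frac = (f[j] - threshold) / (f[j] - f[j + 1])
            end = t[j] + frac * (t[j + 1] - t[j])
        if end - start >= min_hours:
            return float(start)
        i = j + 1
    return None


class ReporterFateClassifier(BaseEstimator):
    """Threshold-and-duration classifier of reporter onset.

    Parameters
    ----------
    threshold : float
        Reporter level (molecules by default) a cell must exceed.
    min_hours : float
        Minimum continuous time above threshold.
    channel : str
        Reporter channel name.

    Attributes
    ----------
    labels_ : FateLabels
        Cycle labels and per-cell onset times.
    """

    def __init__(self, threshold: float = 500.0, min_hours: float = 4.0, channel: str = "FLUC"):
        self.threshold = threshold
        self.min_hours = min_hours
        self.channel = channel

    def fit(self, traces: TraceSet, y=None) -> "ReporterFateClassifier":
        if self.channel not in traces.channels():
            raise ValueError(f"missing reporter channel {self.channel!r}")
        sub = traces.select_channel(self.channel)
        rows = []
        onsets = {}
        for cell, grp in sub.groupby("cell_id", sort=False):
            grp = grp.sort_values("time_h")
            t = grp["time_h"].to_numpy(float)
            f = grp["intensity"].to_numpy(float)
            onset = _onset_time(t, f, self.threshold, self.min_hours)
            onsets[cell] = np.nan if onset is None else onset

            cycles = []
            for cyc, cgrp in grp.groupby("cycle_id", sort=True):
                ct = cgrp["time_h"].to_numpy(float)
                cycles.append((cyc, ct[0], ct[-1]))
            if onset is None:
                turning_idx = None
            else:
                turning_idx = None
                for k, (cyc, t0, t1) in enumerate(cycles):
                    nxt = cycles[k + 1][1] if k + 1 < len(cycles) else np.inf
                    if t0 <= onset < nxt:  # onsets in the gap go to the next cycle
                        turning_idx = k if onset <= t1 else k + 1
                        break
                if turning_idx is not None and turning_idx >= len(cycles):
                    turning_idx = len(cycles) - 1
            for k, (cyc, _, _) in enumerate(cycles):
                if turning_idx is None:
                    label = "negative"
                elif k == turning_idx:
                    label = "turning_positive"
                elif k == turning_idx - 1:
                    label = "before_positive"
                elif k > turning_idx:
                    label = "positive"
                else:
                    label = "negative"
                rows.append((cell, cyc, label))
        self.labels_ = FateLabels(
            labels=pd.DataFrame(rows, columns=["cell_id", "cycle_id", "label"]),
            onset_h=pd.Series(onsets, name="onset_h"),
        )
        return self

    def predict(self, traces: TraceSet) -> pd.DataFrame:
        return self.fit(traces).labels_.labels


def classify_reporter(
    traces: TraceSet,
    threshold: float = 500.0,
    min_hours: float = 4.0,
    channel: str = "FLUC",
) -> FateLabels:
    """Label every (cell, cycle) by the threshold-and-duration reporter rule."""
    clf = ReporterFateClassifier(threshold=threshold, min_hours=min_hours, channel=channel)
    return clf.fit(traces).labels_


@dataclass
class GroupComparison:
    """Per-gridpoint comparison of positive-lineage vs negative cells."""

    grid: np.ndarray  # cumulative progression over the 3-cycle window, [0, 3)
    mean_positive: np.ndarray
    mean_negative: np.ndarray
    pvalues: np.ndarray  # NaN where a group has < min_group cells
    n_positive: int
    n_negative: int
    window_cycles: tuple[str, ...] = ("before_positive", "turning_positive", "positive")


def align_and_compare(
    sync: SynchronizedTraceSet,
    labels: FateLabels,
    min_group: int = 3,
    alignment: str = "absolute_time",
    bh_correct: bool = False,
) -> GroupComparison:
    """Compare SOX2 trajectories of committing vs non-committing cells.

    Positive cells contribute the synchronized window
    (before_positive, turning_positive, first positive) cycle triple;
    negative cells contribute the consecutive cycle triple whose middle
    midpoint (absolute time) is closest to the positive group's mean
    midpoint (``alignment="absolute_time"``) or simply their first three
    cycles (``alignment="cycle_index"``).  Welch's two-sided t-test is run
    at every gridpoint; gridpoints with fewer than ``min_group`` cells in
    either group get a NaN p-value.  ``bh_correct`` applies a
    Benjamini-Hochberg correction across gridpoints (off by default).
    """
    if alignment not in ("absolute_time", "cycle_index"):
        raise ValueError(f"unknown alignment {alignment!r}")
    lab = labels.labels
    g = sync.grid_size

    def window_vector(cell, cycles3):
        parts = []
        for cyc in cycles3:
            try:
                parts.append(sync.values.loc[(cell, cyc)].to_numpy(float))
            except KeyError:
                return None
        return np.concatenate(parts)

    def cycle_midpoint(cell, cyc):
        t0 = sync.start_time_h.loc[(cell, cyc)]
        return t0 + 0.5 * sync.durations_h.loc[(cell, cyc)]

    pos_rows, pos_midpoints = [], []
    for cell, sub in lab.groupby("cell_id", sort=False):
        sub = sub.sort_values("cycle_id")
        seq = sub["label"].tolist()
        cycs = sub["cycle_id"].tolist()
        if "turning_positive" not in seq:
            continue
        k = seq.index("turning_positive")
        if k == 0 or k + 1 >= len(seq):
            continue  # window incomplete at the lineage boundary
        triple = (cycs[k - 1], cycs[k], cycs[k + 1])
        vec = window_vector(cell, triple)
        if vec is None:
            continue
        pos_rows.append(vec)
        pos_midpoints.append(cycle_midpoint(cell, cycs[k]))
    if not pos_rows:
        raise ValueError("no positive cells with a complete three-cycle window")
    target_mid = float(np.mean(pos_midpoints))

    neg_rows = []
    for cell, sub in lab.groupby("cell_id", sort=False):
        if not (sub["label"] == "negative").all():
            continue
        cycs = sorted(sub["cycle_id"].tolist())
        if len(cycs) < 3:
            continue
        triples = [tuple(cycs[i : i + 3]) for i in range(len(cycs) - 2)]
        if alignment == "cycle_index":
            chosen = triples[0]
        else:
            chosen = min(
                triples, key=lambda tr: abs(cycle_midpoint(cell, tr[1]) - target_mid)
            )
        vec = window_vector(cell, chosen)
        if vec is not None:
            neg_rows.append(vec)
    if not neg_rows:
        raise ValueError("no fully negative cells with three complete cycles")

    pos = np.vstack(pos_rows)
    neg = np.vstack(neg_rows)
    grid = np.concatenate([sync.theta + k for k in range(3)])
    pvals = np.full(3 * g, np.nan)
    if len(pos) >= min_group and len(neg) >= min_group:
        res = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    if bh_correct:
        ok = ~np.isnan(pvals)
        if ok.any():
            pvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return GroupComparison(
        grid=grid,
        mean_positive=pos.mean(axis=0),
        mean_negative=neg.mean(axis=0),
        pvalues=pvals,
        n_positive=len(pos),
        n_negative=len(neg),
    )
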