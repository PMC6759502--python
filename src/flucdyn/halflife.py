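"""Single-cell pulse-chase half-life estimation.

A pulse-labelled dye pool decays exponentially; each cell's
background-subtracted intensity trace is normalized to its first frame
and fitted with an exponential decay, giving a per-cell decay rate b and
half-life ln(2)/b.  By default the fit carries a free amplitude nuisance
parameter (f(t) = A exp(-b t)): the first-frame normalization pins the
amplitude only up to the measurement error of that single frame, and
forcing A = 1 lets the normalizer's error leak coherently into b
(inflating the per-cell spread several-fold and biasing half-lives
upward at realistic noise levels).  ``free_amplitude=False`` restores
the strict f(t) = exp(-b t) fit.  When a cell divides during the chase,
the two daughter traces are summed frame-wise so the labelled pool is
conserved across the division.  Cohort comparisons report median
half-lives, the percent change between cohorts, and a p-value from the
normality-guided two-sample test selector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .containers import TraceSet
from .fluctuation import TestResult, compare_two_samples

__all__ = [
    "HalfLifeFit",
    "HalfLifeEstimator",
    "preprocess_decay",
    "fit_half_life",
    "cohort_half_life_change",
    "level_halflife_correlation",
]

LN2 = math.log(2.0)


@dataclass
class HalfLifeFit:
    """Per-cell exponential decay fit."""

    cell_id: str
    b: float  # decay rate, 1/h
    half_life_h: float
    rss: float
    n_points: int
    valid: bool


def preprocess_decay(
    traces: TraceSet, cell_id: str, channel: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract, daughter-sum and first-frame-normalize one cell.

    Daughter traces are recognized by the lineage naming convention
    ``<cell_id>.1`` / ``<cell_id>.2``; from the first daughter frame on,
    the two background-subtracted daughter series are summed frame-wise
    (truncated to their overlap if lengths differ).  Returns
    ``(times_h, normalized_values)`` with times shifted to start at 0.
    """
    data = traces.data
    if channel is not None:
        data = data[data["channel"] == channel]
    parent = data[data["cell_id"] == cell_id].sort_values("frame")
    if parent.empty:
        raise ValueError(f"cell {cell_id!r} not found")
    t = parent["time_h"].to_numpy(float)
    v = parent["intensity"].to_numpy(float) - parent["background"].to_numpy(float)

    d1 = data[data["cell_id"] == f"{cell_id}.1"].sort_values("frame")
    d2 = data[data["cell_id"] == f"{cell_id}.2"].sort_values("frame")
    if len(d1) and len(d2):
        n = min(len(d1), len(d2))
        if len(d1) != len(d2):
            warnings.warn(
                f"daughters of {cell_id!r} have unequal lengths; truncating to overlap",
                stacklevel=2,
            )
        summed = (
            d1["intensity"].to_numpy(float)[:n]
            - d1["background"].to_numpy(float)[:n]
            + d2["intensity"].to_numpy(float)[:n]
            - d2["background"].to_numpy(float)[:n]
        )
        t = np.concatenate([t, d1["time_h"].to_numpy(float)[:n]])
        v = np.concatenate([v, summed])
    elif len(d1) or len(d2):
        d = d1 if len(d1) else d2
        t = np.concatenate([t, d["time_h"].to_numpy(float)])
        v = np.concatenate([v, d["intensity"].to_numpy(float) - d["background"].to_numpy(float)])

    if not (v[0] > 0):
        raise ValueError(f"first-frame value of {cell_id!r} is not positive")
    return t - t[0], v / v[0]


#: decay rates below this (per hour) are indistinguishable from no decay
MIN_DECAY_RATE = 1e-6


def fit_half_life(
    series: np.ndarray,
    times_h: np.ndarray,
    cell_id: str = "",
    free_amplitude: bool = True,
) -> HalfLifeFit:
    """Nonlinear least-squares exponential fit to a normalized decay series.

    With ``free_amplitude`` (default) the model is A * exp(-b t), treating
    the residual first-frame normalization error as a nuisance amplitude;
    with ``free_amplitude=False`` the model is exp(-b t) exactly.  Fits
    with b <= 0 (no decay) or failed convergence are flagged invalid and
    excluded from cohort summaries.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if len(y) < 5:
        raise ValueError("need >= 5 points for a decay fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    # closed-form initial guess from the log-linear slope over positive values
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        b0 = max(-slope, 1e-6)
    else:
        b0 = 0.1
    try:
        if free_amplitude:
            popt, _ = optimize.curve_fit(
                lambda tt, a, b: a * np.exp(-b * tt), t, y, p0=[1.0, b0], maxfev=10000
            )
            a, b = float(popt[0]), float(popt[1])
        else:
            popt, _ = optimize.curve_fit(
                lambda tt, b: np.exp(-b * tt), t, y, p0=[b0], maxfev=10000
            )
            a, b = 1.0, float(popt[0])
        converged = True
    except RuntimeError:
        a, b, converged = float("nan"), float("nan"), False
    if converged:
        rss = float(np.sum((y - a * np.exp(-b * t)) ** 2))
    else:
        rss = float("nan")
    valid = converged and b > MIN_DECAY_RATE
    half_life = LN2 / b if valid else float("nan")
    return HalfLifeFit(cell_id, b, half_life, rss, len(y), valid)


class HalfLifeEstimator(BaseEstimator):
    """Fit per-cell exponential decays across a whole trace set.

    ``fit`` runs :func:`preprocess_decay` + :func:`fit_half_life` on every
    root cell (daughter traces ``*.1`` / ``*.2`` are folded into their
    mothers, never fitted separately).

    Attributes
    ----------
    fits_ : DataFrame
        One row per cell: b_per_h, half_life_h, rss, n_points, valid.
    n_invalid_ : int
        Fits flagged invalid (b <= 0 or non-convergent).
    """

    def __init__(self, channel: str | None = None, free_amplitude: bool = True):
        self.channel = channel
        self.free_amplitude = free_amplitude

    def fit(self, traces: TraceSet, y=None) -> "HalfLifeEstimator":
        cells = [
            c
            for c in pd.unique(traces.data["cell_id"])
            if not (str(c).endswith(".1") or str(c).endswith(".2"))
        ]
        records = []
        for cell in cells:
            t, v = preprocess_decay(traces, cell, channel=self.channel)
            records.append(
                fit_half_life(
                    v, t, cell_id=str(cell), free_amplitude=self.free_amplitude
                )
            )
        self.fits_ = pd.DataFrame(
            {
                "cell_id": [r.cell_id for r in records],
                "b_per_h": [r.b for r in records],
                "half_life_h": [r.half_life_h for r in records],
                "rss": [r.rss for r in records],
                "n_points": [r.n_points for r in records],
                "valid": [r.valid for r in records],
            }
        )
        self.n_invalid_ = int((~self.fits_["valid"]).sum())
        return self

    @property
    def half_lives_(self) -> np.ndarray:
        fits = self.fits_
        return fits.loc[fits["valid"], "half_life_h"].to_numpy(float)


@dataclass
class CohortChange:
    median_ctrl_h: float
    median_treat_h: float
    percent_change: float
    test: TestResult
    n_ctrl: int
    n_treat: int


def _valid_half_lives(fits) -> np.ndarray:
    if isinstance(fits, HalfLifeEstimator):
        return fits.half_lives_
    if isinstance(fits, pd.DataFrame):
        return fits.loc[fits["valid"], "half_life_h"].to_numpy(float)
    values = [f.half_life_h for f in fits if f.valid]
    return np.asarray(values, dtype=float)


def cohort_half_life_change(fits_ctrl, fits_treat) -> CohortChange:
    """Median half-lives, percent change and p-value between two cohorts."""
    ctrl = _valid_half_lives(fits_ctrl)
    treat = _valid_half_lives(fits_treat)
    if len(ctrl) < 3 or len(treat) < 3:
        raise ValueError("each cohort needs >= 3 valid fits")
    med_c = float(np.median(ctrl))
    med_t = float(np.median(treat))
    change = 100.0 * (med_t / med_c - 1.0)
    test = compare_two_samples(treat, ctrl, sides="two")
    return CohortChange(med_c, med_t, change, test, len(ctrl), len(treat))


@dataclass
class CorrelationReport:
    r: float
    pvalue: float
    n: int


def level_halflife_correlation(
    levels, fits, level_norm: float | None = None, halflife_norm: float | None = None
) -> CorrelationReport:
    """Pearson correlation between expression levels and fitted half-lives.

    Both variables are normalized by a cohort mean (the control-cohort
    mean when given, else their own); normalization does not change r or
    the p-value but puts the reported values on a fold-of-average scale.
    """
    levels = np.asarray(levels, dtype=float)
    half_lives = _valid_half_lives(fits)
    if len(levels) != len(half_lives):
        raise ValueError("levels and valid fits must be paired")
    if len(levels) < 3:
        raise ValueError("need >= 3 valid pairs")
    if np.ptp(levels) == 0 or np.ptp(half_lives) == 0:
        raise ValueError("zero-variance input")
    levels = levels / (level_norm if level_norm else levels.mean())
    half_lives = half_lives / (halflife_norm if halflife_norm else half_lives.mean())
    r, p = stats.pearsonr(levels, half_lives)
    return CorrelationReport(float(r), float(p), len(levels))
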