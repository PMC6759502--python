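"""Rank dynamics of single-cell expression levels.

The persistence of expression differences between cells is measured on
ranks: at every timepoint cells are ranked by their (synchronized)
expression level, and the rank-based autocorrelation A(tau) is the
Pearson correlation between the rank column at time 0 and at lag tau --
equivalently the Spearman correlation of the underlying values, hence
invariant to any monotone distortion of the measurement scale.  The
mixing time is the lag at which A first drops below 1/e (located by
linear interpolation between bracketing lags); when the threshold is
never crossed the largest observed lag is reported as a conservative
lower bound.  Standard errors come from bootstrapping cells with
replacement, re-ranking within every resample.

The module also houses the pipeline-wide two-sample test selector: Welch's
unequal-variance t-test unless a Shapiro-Wilk test flags either sample
as non-normal (p < 0.05), in which case a Mann-Whitney U-test is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import SynchronizedTraceSet

__all__ = [
    "RankACF",
    "MixingTimeEstimate",
    "TestResult",
    "RankAutocorrelation",
    "assign_initial_ranks",
    "rank_autocorrelation",
    "mixing_time",
    "compare_two_samples",
]

DEFAULT_THRESHOLD = 1.0 / math.e


@dataclass
class RankACF:
    """Rank autocorrelation curve with bootstrap standard errors."""

    lags: np.ndarray
    acf: np.ndarray  # A(tau)
    se: np.ndarray
    n_boot: int
    seed: int | None
    lag_unit: str = "cycles"


@dataclass
class MixingTimeEstimate:
    """Lag of the 1/e crossing of the rank autocorrelation."""

    tau_mix: float
    threshold: float
    reached: bool
    lag_unit: str = "cycles"


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    test: str  # "welch" or "mann-whitney"
    shapiro_p: tuple[float, float]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SynchronizedTraceSet):
        X, _ = X.per_cell_matrix(1)
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a cells x timepoints matrix")
    return X


def assign_initial_ranks(X) -> pd.DataFrame:
    """Rank cells within every timepoint (1 = lowest; ties get average rank).

    Accepts a :class:`SynchronizedTraceSet`, a DataFrame or a 2D array of
    cells x timepoints; returns the rank matrix ordered by the cells'
    initial (t = 0) rank.
    """
    index = None
    if isinstance(X, SynchronizedTraceSet):
        X, _ = X.per_cell_matrix(1)
    if isinstance(X, pd.DataFrame):
        index = X.index
        columns = X.columns
        X = X.to_numpy(float)
    else:
        X = np.asarray(X, dtype=float)
        columns = np.arange(X.shape[1])
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("rank matrix requires >= 3 cells")
    bad = ~np.isfinite(X)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        cell = index[i] if index is not None else i
        raise ValueError(f"non-finite value for cell {cell!r} at timepoint {columns[j]}")
    ranks = stats.rankdata(X, axis=0, method="average")
    frame = pd.DataFrame(ranks, index=index, columns=columns)
    return frame.sort_values(frame.columns[0])


def _corr_with_first(ranks: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column with the first column."""
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    out = np.full(ranks.shape[1], np.nan)
    ok = norms > 0
    if ok[0]:
        with np.errstate(invalid="ignore"):
            out = (centered[:, [0]] * centered).sum(axis=0) / (norms[0] * norms)
        out[~ok] = np.nan
    out[0] = 1.0
    return out


class RankAutocorrelation(BaseEstimator):
    """Rank-based autocorrelation with bootstrap SE and mixing time.

    Parameters
    ----------
    n_boot : int
        Bootstrap resamples of cells (with replacement); >= 100 for a
        usable SE.
    threshold : float
        Crossing level defining the mixing time (default 1/e).
    random_state : int or None
        Seed of the bootstrap stream.

    Attributes
    ----------
    lags_, acf_, se_ : ndarray
        Lag axis, A(tau) and its bootstrap SE.
    mixing_time_ : float
        Interpolated first crossing below ``threshold`` (or the largest
        lag, as a lower bound, when never crossed).
    mixing_reached_ : bool
        Whether the threshold was actually crossed.
    """

    def __init__(
        self,
        n_boot: int = 1000,
        threshold: float = DEFAULT_THRESHOLD,
        random_state: int | None = None,
    ):
        self.n_boot = n_boot
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y=None, lags=None, lag_unit: str = "cycles") -> "RankAutocorrelation":
        values = _as_matrix(X)
        n_cells, n_time = values.shape
        if n_cells < 3:
            raise ValueError("rank autocorrelation requires >= 3 cells")
        if isinstance(X, pd.DataFrame) and lags is None:
            lags = np.asarray(X.columns, dtype=float)
        lags = np.arange(n_time, dtype=float) if lags is None else np.asarray(lags, float)
        if len(lags) != n_time:
            raise ValueError("lags must match the number of timepoints")
        lags = lags - lags[0]

        ranks = stats.rankdata(values, axis=0, method="average")
        acf = _corr_with_first(ranks)

        rng = np.random.default_rng(self.random_state)
        if self.n_boot >= 1:
            boot = np.empty((self.n_boot, n_time))
            for b in range(self.n_boot):
                idx = rng.integers(0, n_cells, n_cells)
                boot_ranks = stats.rankdata(values[idx], axis=0, method="average")
                boot[b] = _corr_with_first(boot_ranks)
            se = np.nanstd(boot, axis=0, ddof=1)
            se[0] = 0.0
        else:
            se = np.zeros(n_time)

        self.lags_ = lags
        self.acf_ = acf
        self.se_ = se
        self.lag_unit_ = lag_unit
        est = mixing_time(self.result_, threshold=self.threshold)
        self.mixing_time_ = est.tau_mix
        self.mixing_reached_ = est.reached
        return self

    @property
    def result_(self) -> RankACF:
        return RankACF(
            lags=self.lags_,
            acf=self.acf_,
            se=self.se_,
            n_boot=self.n_boot,
            seed=self.random_state,
            lag_unit=self.lag_unit_,
        )


def rank_autocorrelation(
    X,
    n_boot: int = 1000,
    seed: int | None = None,
    lags=None,
    threshold: float = DEFAULT_THRESHOLD,
) -> RankACF:
    """Rank autocorrelation A(tau) with bootstrap SE (cells resampled)."""
    est = RankAutocorrelation(n_boot=n_boot, threshold=threshold, random_state=seed)
    return est.fit(X, lags=lags).result_


def mixing_time(acf: RankACF, threshold: float = DEFAULT_THRESHOLD) -> MixingTimeEstimate:
    """First lag where A(tau) crosses below ``threshold``.

    The crossing is located by linear interpolation between the bracketing
    lags.  If A never drops below the threshold the largest lag is
    returned, flagged as a lower bound (conservative estimate).
    """
    a = np.asarray(acf.acf, dtype=float)
    lags = np.asarray(acf.lags, dtype=float)
    if a.size == 0:
        raise ValueError("empty autocorrelation curve")
    if not (a[0] > threshold):
        raise ValueError("A(0) must exceed the threshold")
    for k in range(1, a.size):
        if np.isnan(a[k]):
            continue
        if a[k] < threshold:
            prev = k - 1
            while np.isnan(a[prev]):
                prev -= 1
            frac = (a[prev] - threshold) / (a[prev] - a[k])
            tau = lags[prev] + frac * (lags[k] - lags[prev])
            return MixingTimeEstimate(float(tau), threshold, True, acf.lag_unit)
    return MixingTimeEstimate(float(lags[-1]), threshold, False, acf.lag_unit)


def compare_two_samples(x, y, sides: str = "two") -> TestResult:
    """Two-sample comparison with the normality-guided test selector.

    Runs Shapiro-Wilk on both samples; if either p < 0.05 a Mann-Whitney
    U-test is used, otherwise Welch's unequal-variance t-test.  ``sides``
    is ``"two"`` or one-sided ``"greater"``/``"less"`` (x versus y);
    ``"one"`` is an alias for ``"greater"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant sample: normality test undefined")
    alternative = {"two": "two-sided", "one": "greater"}.get(sides, sides)
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"invalid sides {sides!r}")
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    if sw_x < 0.05 or sw_y < 0.05:
        res = stats.mannwhitneyu(x, y, alternative=alternative)
        return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney", (sw_x, sw_y))
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return TestResult(float(res.statistic), float(res.pvalue), "welch", (sw_x, sw_y))
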