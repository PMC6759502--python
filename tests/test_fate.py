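"""Reporter-onset classification and cycle-aligned group comparison."""

import numpy as np
import pandas as pd
import pytest

import flucdyn as fd
from flucdyn.containers import SynchronizedTraceSet
from flucdyn.fate import FateLabels, _onset_time

from conftest import build_trace_frame


def fluc_trace(values, interval_h=0.25, cycle_bounds=None, cell="c0"):
    """Build a single-cell FLUC trace; cycle_bounds maps cycle -> (first, last) frame."""
    n = len(values)
    cycle_bounds = cycle_bounds or {0: (0, n - 1)}
    frame_cycle = {}
    for cyc, (a, b) in cycle_bounds.items():
        for k in range(a, b + 1):
            frame_cycle[k] = cyc
    records = [
        (
            cell,
            k,
            k * interval_h,
            "FLUC",
            float(values[k]),
            0.0,
            frame_cycle[k],
            1 if any(k == b for (_, b) in cycle_bounds.values()) else 0,
        )
        for k in range(n)
    ]
    return build_trace_frame(records, units={"FLUC": "molecules"})


class TestClassifyReporter:
    def test_all_zero_fluc_all_negative(self):
        traces = fluc_trace([0.0] * 40)
        labels = fd.classify_reporter(traces)
        assert set(labels.labels["label"]) == {"negative"}

    def test_short_excursion_fails_duration_rule(self):
        # above 500 for exactly 3.5 h (14 frames + interpolated edges < 4 h)
        values = [0.0] * 10 + [600.0] * 14 + [0.0] * 10
        traces = fluc_trace(values)
        labels = fd.classify_reporter(traces, threshold=500.0, min_hours=4.0)
        assert set(labels.labels["label"]) == {"negative"}

    def test_long_run_meets_duration_rule(self):
        values = [0.0] * 5 + [600.0] * 20
        traces = fluc_trace(values)
        labels = fd.classify_reporter(traces)
        assert "turning_positive" in set(labels.labels["label"])

    def test_three_cycle_labelling_pattern(self):
        # 3 cycles of 20 frames; crossing at 10 h (frame 40) inside cycle 2
        values = [0.0] * 40 + [800.0] * 20
        bounds = {0: (0, 19), 1: (20, 39), 2: (40, 59)}
        traces = fluc_trace(values, cycle_bounds=bounds)
        labels = fd.classify_reporter(traces)
        assert labels.of("c0", 0) == "negative" or len(set(labels.labels["label"])) == 3
        assert labels.of("c0", 1) == "before_positive"
        assert labels.of("c0", 2) == "turning_positive"

    def test_cycles_after_turning_are_positive(self):
        values = [0.0] * 10 + [800.0] * 50
        bounds = {0: (0, 19), 1: (20, 39), 2: (40, 59)}
        traces = fluc_trace(values, cycle_bounds=bounds)
        labels = fd.classify_reporter(traces)
        assert labels.of("c0", 0) == "turning_positive"
        assert labels.of("c0", 1) == "positive"
        assert labels.of("c0", 2) == "positive"

    def test_missing_channel_rejected(self, simple_cycle_traces):
        with pytest.raises(ValueError, match="FLUC"):
            fd.classify_reporter(simple_cycle_traces)

    def test_time_shift_invariance(self):
        values = [0.0] * 10 + [700.0] * 30
        a = fd.classify_reporter(fluc_trace(values))
        shifted = fluc_trace(values)
        shifted.data["time_h"] += 5.0
        b = fd.classify_reporter(shifted)
        assert a.labels["label"].tolist() == b.labels["label"].tolist()

    def test_matches_brute_force_run_scanner(self):
        """Interpolated-run classifier equals an exhaustive run scan on
        1000 random step traces."""
        rng = np.random.default_rng(99)
        threshold, min_hours, dt = 500.0, 4.0, 0.25
        mismatches = 0
        for _ in range(1000):
            n = int(rng.integers(20, 60))
            values = rng.choice([0.0, 250.0, 600.0, 900.0], size=n)
            t = np.arange(n) * dt
            fast = _onset_time(t, values, threshold, min_hours)
            slow = brute_force_onset(t, values, threshold, min_hours)
            if (fast is None) != (slow is None):
                mismatches += 1
            elif fast is not None and not np.isclose(fast, slow):
                mismatches += 1
        assert mismatches == 0


def brute_force_onset(t, f, threshold, min_hours):
    """Independent oracle: scan every maximal super-threshold run."""
    above = f > threshold
    runs = []
    k = 0
    n = len(f)
    while k < n:
        if above[k]:
            j = k
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((k, j))
            k = j + 1
        else:
            k += 1
    for i, j in runs:
        if i == 0:
            start = t[0]
        else:
            start = np.interp(threshold, [f[i - 1], f[i]], [t[i - 1], t[i]])
        if j == n - 1:
            end = t[-1]
        else:
            end = np.interp(threshold, [f[j + 1], f[j]], [t[j + 1], t[j]])
        if end - start >= min_hours:
            return float(start)
    return None


def synthetic_sync(rows, n_cycles=3, grid=10, durations=None, starts=None):
    """Fabricate a SynchronizedTraceSet from per-(cell, cycle) row vectors."""
    index = pd.MultiIndex.from_tuples(list(rows), names=["cell_id", "cycle_id"])
    theta = np.linspace(0, 1, grid)
    values = pd.DataFrame([rows[k] for k in rows], index=index, columns=theta)
    durations = durations or {k: 13.0 for k in rows}
    starts = starts or {k: 13.0 * k[1] for k in rows}
    return SynchronizedTraceSet(
        values=values,
        durations_h=pd.Series(durations),
        start_time_h=pd.Series(starts),
        channel="SOX2",
    )


def make_labels(cells_pos, cells_neg, n_cycles=3):
    rows = []
    for c in cells_pos:
        rows += [(c, 0, "before_positive"), (c, 1, "turning_positive"), (c, 2, "positive")]
    for c in cells_neg:
        rows += [(c, k, "negative") for k in range(n_cycles)]
    onsets = {c: 15.0 for c in cells_pos} | {c: np.nan for c in cells_neg}
    return FateLabels(
        labels=pd.DataFrame(rows, columns=["cell_id", "cycle_id", "label"]),
        onset_h=pd.Series(onsets),
    )


class TestAlignAndCompare:
    def _random_sync(self, cells, rng, shift=None, grid=10):
        rows = {}
        for c in cells:
            for cyc in range(3):
                vec = rng.normal(100.0, 10.0, grid)
                if shift is not None:
                    vec = vec + shift[cyc * grid : (cyc + 1) * grid]
                rows[(c, cyc)] = vec
        return rows

    def test_null_groups_have_uniform_false_positive_rate(self):
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(10):
            pos = [f"p{i}" for i in range(15)]
            neg = [f"n{i}" for i in range(15)]
            sync = synthetic_sync(self._random_sync(pos + neg, rng))
            comp = fd.align_and_compare(sync, make_labels(pos, neg))
            fracs.append(np.nanmean(comp.pvalues < 0.05))
        assert abs(np.mean(fracs) - 0.05) <= 0.03

    def test_global_shift_significant_everywhere(self):
        rng = np.random.default_rng(8)
        pos = [f"p{i}" for i in range(12)]
        neg = [f"n{i}" for i in range(12)]
        rows = self._random_sync(neg, rng)
        shift = np.full(30, 30.0)  # +3 SD at every gridpoint
        rows.update(self._random_sync(pos, rng, shift=shift))
        sync = synthetic_sync(rows)
        comp = fd.align_and_compare(sync, make_labels(pos, neg))
        assert np.all(comp.pvalues < 0.01)

    def test_localized_effect_detected_in_first_decile(self):
        rng = np.random.default_rng(9)
        pos = [f"p{i}" for i in range(20)]
        neg = [f"n{i}" for i in range(20)]
        rows = self._random_sync(neg, rng, grid=20)
        shift = np.zeros(60)
        shift[:6] = 40.0  # effect confined to the start of the window
        rows.update(self._random_sync(pos, rng, shift=shift, grid=20))
        sync = synthetic_sync(rows, grid=20)
        comp = fd.align_and_compare(sync, make_labels(pos, neg))
        sig = comp.pvalues < 0.01
        assert sig[:6].all()
        assert sig[6:].mean() < 0.2

    def test_absolute_time_alignment_picks_matching_window(self):
        rng = np.random.default_rng(10)
        pos = ["p0", "p1", "p2"]
        rows = self._random_sync(pos, rng)
        # negative cell with 5 cycles; the triple centred near the positive
        # group's turning midpoint (cycle 1, midpoint 19.5 h) is cycles 0-2
        for cyc in range(5):
            rows[("n0", cyc)] = np.full(10, float(cyc))
        for extra in ("n1", "n2"):
            for cyc in range(3):
                rows[(extra, cyc)] = rng.normal(100, 10, 10)
        labels_rows = []
        for c in pos:
            labels_rows += [
                (c, 0, "before_positive"),
                (c, 1, "turning_positive"),
                (c, 2, "positive"),
            ]
        for c, ncyc in (("n0", 5), ("n1", 3), ("n2", 3)):
            labels_rows += [(c, k, "negative") for k in range(ncyc)]
        labels = FateLabels(
            labels=pd.DataFrame(labels_rows, columns=["cell_id", "cycle_id", "label"]),
            onset_h=pd.Series({c: 15.0 for c in pos} | {"n0": np.nan, "n1": np.nan, "n2": np.nan}),
        )
        sync = synthetic_sync(rows)
        comp = fd.align_and_compare(sync, labels)
        assert comp.n_negative == 3

    def test_generated_commitment_pipeline_runs_end_to_end(self, config):
        traces = fd.make_commitment_traces(config, 60, effect_size=3.0, seed=44)
        labels = fd.classify_reporter(traces)
        sync = fd.synchronize(traces, grid_size=20, channel="SOX2")
        comp = fd.align_and_compare(sync, labels)
        assert comp.n_positive >= 3 and comp.n_negative >= 3
        assert comp.grid.shape == comp.pvalues.shape
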