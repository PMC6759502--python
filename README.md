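# flucdyn

Single-cell dynamics of endogenous pluripotency transcription factors
(SOX2/OCT4) fluctuate slowly: nuclear concentrations span a 2–3-fold
range per cell, cells keep their expression rank for about one cell
cycle, and these fluctuations bias both protein stability of partner
factors and germ-layer fate commitment.  `flucdyn` is a tested,
reusable implementation of the computational side of that analysis for
researchers working with single-cell time-lapse and flow-cytometry
data, together with synthetic-data generators that reproduce the
statistical structure every stage assumes — so the whole pipeline runs
and is validated without any experimental download.

## What it computes

* **Trace simulation** — per cell, log nuclear concentration x(t)
  follows a discretized mean-reverting (Ornstein–Uhlenbeck) process,
  x(t+Δ) = x(t)·e^(−Δ/τ) + ε with ε ~ N(0, s²(1−e^(−2Δ/τ))); molecule
  number N(t) = c(t)·V(θ), with nuclear volume V(θ) = v₀(1+θ) growing
  linearly over cell-cycle progression θ ∈ [0,1] and halving at
  division.  Pulse-chase decays, reporter-commitment traces, snapshot
  populations with DNA content, and NLUC–FLUC calibration frames are
  generated by the same module (`make_*` functions).
* **Absolute calibration** — `MoleculeCalibrator` converts intensities
  to molecule numbers using co-imaged cells carrying a 1:1 NLUC–FLUC
  fusion (median per-cell κ̂ = intensity units per molecule).
* **In-silico synchronization** — `CellCycleSynchronizer` resamples
  each complete cycle onto a shared θ grid by linear interpolation of
  the time variable; `to_concentration` applies the linear
  nuclear-volume model (conc = N / (N_A · V(θ))).
* **Rank dynamics** — `RankAutocorrelation` computes the rank-based
  autocorrelation A(τ) (Spearman correlation between t = 0 and lag τ),
  bootstrap SEs over cells, and the **mixing time**: the lag of the
  first 1/e crossing.
* **Half-lives** — per-cell exponential fits of first-frame-normalized
  pulse-chase decays (t½ = ln 2 / b), with frame-wise daughter summing
  across divisions, plus cohort change reports and the pipeline-wide
  two-sample test selector (Welch, or Mann–Whitney when Shapiro–Wilk
  flags non-normality).
* **Fate classification** — a cell turns reporter-positive when its
  FLUC signal exceeds 500 molecules continuously for ≥ 4 h; cycles are
  labelled negative / before-positive / turning-positive / positive
  and SOX2 trajectories of committing vs non-committing cells are
  compared per θ-gridpoint.
* **Gating** — DNA-content G1/S gating (Gaussian 2N peak + S/G2
  continuum mixture), quantile windows (intermediate ~25 %, top/bottom
  ~30 %), the four SOX2×OCT4 corner windows (~20 % each, solved on the
  empirical joint distribution), and the 8-h post-sort mean-reversion
  readout.
* **Region grouping** — the three-contrast differential-accessibility
  rule (adjusted p < 0.1 in ≥ 1 contrast; OCT4- / SOX2- / co-regulated
  by significance pattern, direction by fold-change sign) and BED
  interval overlap fractions.

## Worked example

```python
import numpy as np
import flucdyn as fd

config = fd.GeneratorConfig(seed=7)

# pulse-chase half-life recovery (truth: 8.1 h)
decay = fd.make_decay_traces(config, n_cells=20, half_life_h=8.1)
fits = fd.HalfLifeEstimator().fit(decay)
print(f"mean half-life: {fits.half_lives_.mean():.2f} h "
      f"({len(fits.half_lives_)} valid fits)")

# fluctuation amplitude and mixing time on calibrated concentrations
traces = fd.make_fluctuation_traces(config, n_cells=200, n_cycles=2)
cal = fd.make_calibration_frames(config, n_cells=50)
molecules = fd.MoleculeCalibrator().fit(cal).transform(traces)
conc = fd.to_concentration(fd.synchronize(molecules), config.v0_fl)
matrix, _ = conc.per_cell_matrix(n_cycles=2)
ratios = matrix.max(axis=1) / matrix.min(axis=1)
print(f"median max/min concentration ratio: {np.median(ratios):.2f}")

acf = fd.RankAutocorrelation(n_boot=500, random_state=1).fit(matrix)
print(f"mixing time: {acf.mixing_time_:.2f} cell cycles "
      f"(threshold crossed: {acf.mixing_reached_})")
```

Output:

```
mean half-life: 8.08 h (20 valid fits)
median max/min concentration ratio: 2.54
mixing time: 0.72 cell cycles (threshold crossed: True)
```

The fitted half-lives recover the 8.1-h simulation truth; the median
per-cell concentration range falls in the 2–3-fold band; and the rank
autocorrelation of this particular 200-cell cohort loses its initial
ordering within about one cell cycle (the estimate fluctuates around
0.9 cycles between cohorts — see `docs/methods.md`).

A command-line interface mirrors the library
(`flucdyn simulate|calibrate|sync|concentration|mixing|halflife|fate|gate|revert|regions`),
reading and writing plain TSV/JSON with deterministic provenance
headers.

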