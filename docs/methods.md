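# Methods

This note documents the models behind `flucdyn`, the parameters that
matter, the numerical choices, and what the synthetic-data generators do
and do not emulate.

## Fluctuation model

The generator treats each cell's log nuclear concentration as a
stationary mean-reverting (Ornstein–Uhlenbeck) process, discretized
exactly at the sampling interval Δ:

    x(t+Δ) = x(t) · e^(−Δ/τ) + ε,   ε ~ N(0, s²(1 − e^(−2Δ/τ)))

with stationary SD `log_sd = s` and relaxation time `relax_time_h = τ`.
This is the minimal process that is positive on the concentration scale
(c = c₀·eˣ), stationary, and has a single tunable memory timescale.  It
was chosen to reproduce two observed phenomena: concentration ranges of
2–3-fold per cell over two cycles and rank mixing on the timescale of
one cell cycle.  With the defaults `log_sd = 0.3` and `τ = 13 h` (one
mean cycle) both hold; these two defaults are calibrated to the
phenomenology, not measured constants.

Molecule numbers follow N(t) = c(t) · V(θ(t)) · 0.6022 (molecules per
nM·fL), with nuclear volume growing linearly over the cycle,
V(θ) = v₀(1+θ).  Linear doubling is the unique growth law for which a
protein that doubles its copy number over the cycle has constant
concentration; the package relies on this consistency (noise-free
doubling traces are bit-flat after concentration conversion, an exact
test).  `v0_fl = 500 fL` is a placeholder of the right order for an ES
cell nucleus and is a required, overridable parameter; concentrations
scale inversely with it.  `base_conc_nm = 150 nM` sets copy numbers in
the tens of thousands at these volumes.

Cycle durations are Normal(13 h, 1.5 h) truncated below at half the
mean — the imaging literature reports no precise duration for these
cells, so these are realistic placeholders — and rounded to a whole
number of 15-min frames so every division lands on a frame.  Each cycle
is observed from θ = 0 (first frame after division) to θ = 1 (division
frame, flagged); the next cycle starts one frame later.  This convention
keeps time strictly increasing per cell while giving every complete
cycle both boundary samples, which the synchronizer requires.  Division
halves N and V deterministically; partitioning noise is not modelled.

Measurement noise is mean-one multiplicative lognormal with CV
`obs_cv = 0.1`, applied per frame, plus a recorded additive background.
Observed intensity is `kappa · N · noise + background`, with `kappa` the
detection constant (intensity units per molecule) that the calibration
module estimates.

## Calibration

Calibration cells carry a 1:1 NLUC–FLUC fusion with a known FLUC
detection constant φ_f, so molecules M = FLUC/φ_f and κ = NLUC/M per
cell.  κ̂ is the median over cells (robust: a single corrupted
calibration cell out of five leaves it unchanged, an asserted property),
with the median absolute deviation as the dispersion report.  Conversion
uses one factor per movie; per-frame drift is handled separately by the
population detrender, which divides all traces by the
first-frame-normalized population mean.

## Synchronization and rank dynamics

Each complete cycle is linearly interpolated onto θ_k = k/(G−1), G = 100
by default; cycles lacking a boundary are excluded and counted, never
extrapolated.  Ranks are recomputed per gridpoint (ties averaged), so
all rank statistics are invariant to any monotone distortion of the
intensity scale — the reason for preferring rank- over value-based
autocorrelation on microscopy data.

The rank autocorrelation uses a fixed origin (τ = 0 column against each
lag), and its SE is the SD of the curve over bootstrap resamples of
cells (re-ranked within each resample); the SE at lag 0 is exactly 0.
The mixing time is the first crossing below 1/e, located by linear
interpolation between bracketing lags; if the curve never crosses, the
largest lag is returned flagged as a lower bound (the conservative
convention).  The threshold is configurable.

Two properties of this estimator matter for interpretation.  First,
measurement noise attenuates the observed autocorrelation by roughly
s²/(s²+σ_n²) (≈ 0.90 at the defaults), so the measured crossing sits
near 0.9 relaxation times rather than 1.0.  Second, at realistic cohort
sizes the ACF level carries substantial cell-sampling variance: across
59-cell cohorts the crossing estimate has an SD of ≈ 0.13 cycles around
a mean of ≈ 0.91.  Tests of the generator–estimator link therefore
average over a few replicate cohorts rather than widening tolerance
bands.

## Half-life fitting

Decay traces are background-subtracted, daughters are summed frame-wise
from the division on (truncated to their overlap if unequal), and the
series is normalized to its first frame.  The decay rate is fitted by
nonlinear least squares of A·e^(−bt); t½ = ln 2 / b; fits with b ≤ 0 or
failed convergence are flagged invalid and excluded (never clipped).

The amplitude A is a deliberate nuisance parameter.  Normalizing by a
single measured frame pins the amplitude only up to that frame's
measurement error; forcing A = 1 makes this error leak coherently into
b — in simulation at 10 % frame noise it inflates the per-cell half-life
SD from 0.21 h to 1.55 h and biases the mean upward by ≈ 3 %, enough to
break 5 %-level cohort recovery.  With the free amplitude, recovery of
8.1 h and 7.8 h truths from 20-cell cohorts is unbiased with ≈ 0.6 %
standard error, and a simulated 1.5-fold stabilization is read out as a
+50 % median change.  `free_amplitude=False` restores the strict
fixed-amplitude fit for comparison with legacy analyses.

## Fate classification and group comparison

The reporter rule (≥ 500 molecules sustained for ≥ 4 h, both
configurable) is evaluated with run boundaries placed at linearly
interpolated threshold crossings, because sampling (8–17 min frames) is
coarser than the rule; a run's duration is measured between interpolated
crossings.  The classifier is checked against a brute-force run scanner
on random step traces.  Cycle labels follow the lineage: the cycle
containing onset is turning-positive, the one immediately before is
before-positive, later cycles positive, everything else negative.

For the trajectory comparison, committing cells contribute their
(before, turning, after) synchronized cycle triple; non-committing cells
contribute the consecutive triple whose middle-cycle midpoint in
absolute time is closest to the positive group's mean midpoint (an
alternative cycle-index alignment is available).  Welch's two-sided test
runs per gridpoint with no multiple-testing correction by default,
mirroring per-point reporting; a Benjamini–Hochberg option exists.

## Gating

DNA-content gating fits, by EM, a two-component model to log DNA: a
Gaussian 2N peak (weight, mean, SD free) plus an S/G2 continuum modelled
as a uniform on [2N, 4N] convolved with the same measurement SD.  G1 is
the peak-assigned region within ±2 SD of the peak; S is the
continuum-assigned region up to 1.9× the peak.  Degenerate inputs (no
peak, or a peak as wide as the S/G2 span) raise an error suggesting the
manual-bounds override, which is a plain interval test.

Quantile windows are rank-based with a stable-sort tie rule (lower
original index first), so an f-window selects exactly round(f·n) events
on distinct values and is deterministic under ties.  Corner windows
(SOX2 high/low × OCT4 high/low) solve, per corner, a single symmetric
outer-tail fraction q for both channels by bisection on the empirical
joint distribution so each corner captures the target fraction
(default 20 %); q is capped at 0.5, which keeps the four masks disjoint,
and infeasible targets (strong channel dependence) raise an error
advising a smaller fraction.  For this reason the snapshot generator
draws SOX2/OCT4 levels independently of DNA content with a weak default
correlation (0.2): a strong common cell-size factor would make four
disjoint 20 % corners geometrically impossible.

The mean-reversion experiment sorts high/low windows on a noisy
observation, propagates each cell's latent log-level forward under the
OU dynamics, and reports the shrinkage of the high–low separation.
Shrinkage is measured on the latent levels and on a *fresh* post-sort
baseline observation — not on the sort signal itself, whose
selection-biased noise would attenuate the baseline by s²/(s²+σ_n²) and
distort the shrinkage factor away from the theoretical e^(−Δt/τ).  The
one-sided Welch p-value for the remaining high-vs-low difference is
computed on observed values.

## Region grouping

Significance is adjusted p < `fdr` (default 0.1) per contrast.
Direction for co-regulated regions comes from contrast C (the
combined-sort contrast) when C is significant; otherwise from the
concordant O/S sign, falling back to the larger |logFC| when O and S
disagree (configurable).  logFC exactly 0 counts as down; adjusted
p-values outside [0,1] are rejected.  Differential testing itself
(normalization, moderated statistics) is out of scope — the module
consumes its output table.  Interval overlap is half-open, ≥ 1 bp, via
pyranges, and is checked against an all-pairs scan.

## What the generators do not emulate

No image formation or segmentation noise, no lineage-tracking errors or
cell loss, no mRNA dynamics, no division partitioning noise, no
dye-labelling kinetics (labelling efficiency, residual free dye), no
spectral spillover or FCS artefacts, and no dependence of protein levels
on cell size/DNA content.  Passing tests therefore validate the
statistical machinery under the stated model, not robustness to those
real-data failure modes; the readers/validators (monotone-time checks,
unit annotations, excluded-cycle counts) are where real data will first
disagree.

## Problem sizes and determinism

Validation runs use 20-cell decay cohorts, 59–200-cell fluctuation
cohorts over two cycles, 10⁴–10⁵ snapshot events, and 10³–10⁴ random
tables for the oracle-equivalence checks — sizes at which every check
completes in seconds while matching the cohort sizes of the analyses
they validate.  All randomness flows from `numpy.random.default_rng`
seeded from configuration; identical seeds give bit-identical outputs,
including serialized files (provenance headers carry the version and
seed but no timestamp).
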