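"""Synthetic single-cell data generators.

Every downstream stage of the pipeline is exercised on data produced here,
so the generators encode the statistical structure the analyses assume:

* **Fluctuation traces** -- each cell's log nuclear concentration follows a
  discretized mean-reverting (Ornstein-Uhlenbeck) process with stationary
  SD ``log_sd`` and relaxation time ``relax_time_h``; molecule number is
  concentration times a nuclear volume that grows linearly from ``v0`` to
  ``2 v0`` over the cycle, halving at division.  With the defaults
  (log_sd 0.3, relaxation = one cell cycle) concentrations span a median
  2-3-fold range per cell and ranks mix on the timescale of one cycle,
  while molecule numbers double over each cycle on average.
* **Decay traces** -- pulse-chase dye decays, exponential with a chosen
  half-life, optionally with a division that splits intensity between two
  tracked daughters.
* **Commitment traces** -- a SOX2 channel plus a FLUC differentiation
  reporter that ramps up in the cycle where a cell commits; commitment is
  logistic in the standardized SOX2 level at cycle start.
* **Snapshot populations** -- flow-cytometry-like events with a 2N DNA
  peak plus a 2N-4N S/G2 continuum and correlated bivariate-lognormal
  SOX2/OCT4 levels.
* **Calibration frames** -- cells carrying a 1:1 NLUC-FLUC fusion, the
  input of the absolute-molecule-number calibration.

All randomness comes from ``numpy.random.default_rng`` seeded from the
configuration; identical seeds give bit-identical tables.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import ConfigError, GeneratorConfig
from .containers import TRACE_COLUMNS, CalibrationSet, TraceSet

__all__ = [
    "MOLECULES_PER_NM_FL",
    "make_fluctuation_traces",
    "make_decay_traces",
    "make_commitment_traces",
    "make_snapshot_population",
    "make_calibration_frames",
    "generate_fluctuation_traces",
    "generate_decay_traces",
    "generate_commitment_traces",
    "generate_snapshot_population",
    "generate_calibration_frames",
]

#: molecules contained in 1 fL at 1 nM: 1e-9 mol/L * N_A / mol * 1e-15 L/fL
MOLECULES_PER_NM_FL = 1e-9 * 6.02214076e23 * 1e-15


def _rng(config: GeneratorConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config.seed if seed is None else seed)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def _draw_cycle_frames(
    rng: np.random.Generator, config: GeneratorConfig, n: int
) -> np.ndarray:
    """Cycle lengths in whole sampling frames (steps), truncated-normal in hours.

    Durations below half the mean are redrawn (truncation by resampling) and
    rounded to a whole number of frames so that division lands on a frame.
    """
    durations = np.empty(n)
    lo = 0.5 * config.cycle_mean_h
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(config.cycle_mean_h, config.cycle_sd_h, remaining.size)
        ok = draw >= lo
        durations[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    steps = np.maximum(np.rint(durations / config.interval_h).astype(int), 2)
    return steps


def _simulate_cell_cycles(
    rng: np.random.Generator,
    config: GeneratorConfig,
    n_cycles: int,
    channel: str,
    cell_id: str,
    collect_cycle_start_z: list | None = None,
):
    """Simulate one cell's fluctuation trace over ``n_cycles`` complete cycles.

    Returns the per-frame record rows plus the per-frame latent molecule
    numbers (noise-free ground truth, used internally by the commitment
    generator)."""
    steps = _draw_cycle_frames(rng, config, n_cycles)
    a_step = math.exp(-config.interval_h / config.relax_time_h)
    innov_sd = config.log_sd * math.sqrt(max(0.0, 1.0 - a_step * a_step))
    x = rng.normal(0.0, config.log_sd) if config.log_sd > 0 else 0.0

    rows = []
    truth = []
    t = 0.0
    frame = 0
    for cycle, n_steps in enumerate(steps):
        if collect_cycle_start_z is not None:
            collect_cycle_start_z.append(x / config.log_sd if config.log_sd > 0 else 0.0)
        for j in range(n_steps + 1):
            theta = j / n_steps
            conc = config.base_conc_nm * math.exp(x)
            volume = config.v0_fl * (1.0 + theta)
            molecules = conc * volume * MOLECULES_PER_NM_FL
            rows.append(
                (
                    cell_id,
                    frame,
                    t,
                    channel,
                    config.kappa * molecules,  # noise applied vectorized later
                    config.bg_level,
                    cycle,
                    1 if j == n_steps else 0,
                )
            )
            truth.append(molecules)
            # advance the latent log-concentration to the next frame
            if config.log_sd > 0:
                x = a_step * x + rng.normal(0.0, innov_sd)
            t += config.interval_h
            frame += 1
    return rows, truth


def make_fluctuation_traces(
    config: GeneratorConfig,
    n_cells: int,
    n_cycles: int,
    *,
    channel: str = "SOX2",
    seed: int | None = None,
) -> TraceSet:
    """Generate mean-reverting concentration fluctuation traces.

    Each cell is observed over ``n_cycles`` complete cell cycles at
    ``config.interval_h`` sampling; the first frame of a cycle is theta=0
    (just after division) and the division frame carries theta=1 and
    ``division_flag=1``.  Observed intensity is ``kappa * N`` times
    mean-one lognormal noise, plus the recorded additive background.
    """
    if n_cells < 1 or n_cycles < 1:
        raise ConfigError("n_cells and n_cycles must be >= 1")
    rng = _rng(config, seed)
    all_rows: list = []
    for i in range(n_cells):
        rows, _ = _simulate_cell_cycles(rng, config, n_cycles, channel, f"c{i:04d}")
        all_rows.extend(rows)
    data = pd.DataFrame(all_rows, columns=TRACE_COLUMNS)
    noise = _lognormal_factors(rng, config.obs_cv, len(data))
    data["intensity"] = data["intensity"].to_numpy() * noise + data["background"].to_numpy()
    return TraceSet(data, units={channel: "au"})


def make_decay_traces(
    config: GeneratorConfig,
    n_cells: int,
    half_life_h: float,
    duration_h: float = 12.5,
    interval_h: float | None = None,
    division_prob: float = 0.0,
    *,
    channel: str = "dye",
    n0_mean: float = 2000.0,
    n0_cv: float = 0.3,
    seed: int | None = None,
) -> TraceSet:
    """Generate pulse-chase exponential decay traces.

    Signal decays as ``N0 * exp(-b t)`` with ``b = ln(2) / half_life_h``
    (``half_life_h=inf`` gives a constant trace), observed through
    multiplicative lognormal noise and an additive background.  With
    probability ``division_prob`` a cell divides at a random interior
    frame; the mother row at the division frame is flagged and the two
    daughters (cell ids ``<cell>.1`` and ``<cell>.2``) partition the
    remaining signal and are recorded separately.
    """
    if not (half_life_h > 0):
        raise ConfigError("half_life_h must be > 0")
    interval_h = config.interval_h if interval_h is None else interval_h
    if interval_h >= duration_h:
        raise ConfigError("interval_h must be smaller than duration_h")
    if not (0.0 <= division_prob <= 1.0):
        raise ConfigError("division_prob must be a probability")
    rng = _rng(config, seed)
    b = 0.0 if math.isinf(half_life_h) else math.log(2.0) / half_life_h
    times = np.arange(0.0, duration_h + 1e-9, interval_h)
    n_frames = len(times)

    rows: list = []
    for i in range(n_cells):
        cell = f"c{i:04d}"
        n0 = n0_mean * _lognormal_factors(rng, n0_cv, 1)[0]
        signal = n0 * np.exp(-b * times)
        divides = n_frames >= 6 and rng.random() < division_prob
        if divides:
            div_frame = int(rng.integers(2, n_frames - 3))
            frac = rng.uniform(0.4, 0.6)
        else:
            div_frame = n_frames  # no division
            frac = 0.5

        def emit(cid: str, frames: np.ndarray, sig: np.ndarray, cycle: int, div_at: int):
            noise = _lognormal_factors(rng, config.obs_cv, len(frames))
            for k, f in enumerate(frames):
                rows.append(
                    (
                        cid,
                        int(f),
                        times[f],
                        channel,
                        config.kappa * sig[k] * noise[k] + config.bg_level,
                        config.bg_level,
                        cycle,
                        1 if f == div_at else 0,
                    )
                )

        mother_frames = np.arange(0, min(div_frame + 1, n_frames))
        emit(cell, mother_frames, signal[mother_frames], 0, div_frame)
        if divides:
            daughter_frames = np.arange(div_frame + 1, n_frames)
            emit(cell + ".1", daughter_frames, frac * signal[daughter_frames], 1, -1)
            emit(cell + ".2", daughter_frames, (1.0 - frac) * signal[daughter_frames], 1, -1)

    data = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    return TraceSet(data, units={channel: "au"})


def make_commitment_traces(
    config: GeneratorConfig,
    n_cells: int,
    effect_size: float = 2.0,
    onset_threshold_frac: float = 0.3,
    *,
    n_cycles: int = 3,
    plateau_molecules: float = 2000.0,
    sox2_channel: str = "SOX2",
    fluc_channel: str = "FLUC",
    seed: int | None = None,
    return_truth: bool = False,
):
    """Generate paired SOX2 + differentiation-reporter (FLUC) traces.

    Each cell carries a fluctuating SOX2 channel.  At the start of every
    cycle the cell commits with probability
    ``sigmoid(logit(onset_threshold_frac) + effect_size * z)`` where ``z``
    is its standardized latent SOX2 log-level, so ``effect_size`` is the
    log-odds change per stationary SD.  A committed cell ramps its FLUC
    signal (reported in molecules) linearly from 0 at the committing
    cycle's start to ``plateau_molecules`` at mid-cycle, staying at plateau
    afterwards.
    """
    if n_cells < 2:
        raise ConfigError("n_cells must be >= 2")
    if not (0.0 < onset_threshold_frac < 1.0):
        raise ConfigError("onset_threshold_frac must be in (0, 1)")
    rng = _rng(config, seed)
    intercept = math.log(onset_threshold_frac / (1.0 - onset_threshold_frac))

    all_rows: list = []
    truth_rows: list = []
    for i in range(n_cells):
        cell = f"c{i:04d}"
        start_z: list = []
        rows, _ = _simulate_cell_cycles(
            rng, config, n_cycles, sox2_channel, cell, collect_cycle_start_z=start_z
        )
        noise = _lognormal_factors(rng, config.obs_cv, len(rows))
        rows = [
            row[:4] + (row[4] * noise[k] + row[5],) + row[5:] for k, row in enumerate(rows)
        ]
        all_rows.extend(rows)

        # commitment decision at each cycle start
        commit_cycle = -1
        for cycle, z in enumerate(start_z):
            p = 1.0 / (1.0 + math.exp(-(intercept + effect_size * z)))
            if rng.random() < p:
                commit_cycle = cycle
                break
        truth_rows.append((cell, commit_cycle, start_z))

        # FLUC channel on the same frames
        frame_info = [(r[1], r[2], r[6], r[7]) for r in rows]  # frame, t, cycle, div
        cycle_bounds: dict[int, tuple[float, float]] = {}
        for _, t, cyc, _ in frame_info:
            lo, hi = cycle_bounds.get(cyc, (t, t))
            cycle_bounds[cyc] = (min(lo, t), max(hi, t))
        fluc_noise = _lognormal_factors(rng, config.obs_cv, len(frame_info))
        for k, (frame, t, cyc, div) in enumerate(frame_info):
            level = 0.0
            if commit_cycle >= 0:
                t0, t1 = cycle_bounds[commit_cycle]
                ramp_end = t0 + 0.5 * (t1 - t0)
                if t >= ramp_end:
                    level = plateau_molecules
                elif t > t0:
                    level = plateau_molecules * (t - t0) / (ramp_end - t0)
            all_rows.append(
                (cell, frame, t, fluc_channel, level * fluc_noise[k], 0.0, cyc, div)
            )

    data = pd.DataFrame(all_rows, columns=TRACE_COLUMNS)
    traces = TraceSet(data, units={sox2_channel: "au", fluc_channel: "molecules"})
    if return_truth:
        truth = pd.DataFrame(
            [(c, k) for c, k, _ in truth_rows], columns=["cell_id", "commit_cycle"]
        )
        return traces, truth
    return traces


def make_snapshot_population(
    config: GeneratorConfig,
    n_events: int,
    g1_fraction: float = 0.6,
    *,
    correlation: float = 0.2,
    dna_2n: float = 100.0,
    dna_cv: float = 0.05,
    level_scale: float = 1000.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a flow-cytometry-like snapshot event table.

    DNA content mixes a lognormal 2N peak (G1) with a 2N-4N S/G2 continuum;
    SOX2/OCT4 levels are correlated bivariate lognormal (stationary log-SD
    ``config.log_sd``) observed through the usual multiplicative noise.
    Levels are drawn independently of DNA content.
    """
    if n_events < 1:
        raise ConfigError("n_events must be >= 1")
    if not (0.0 < g1_fraction <= 1.0):
        raise ConfigError("g1_fraction must be in (0, 1]")
    if not (-1.0 <= correlation <= 1.0):
        raise ConfigError("correlation must lie in [-1, 1]")
    rng = _rng(config, seed)

    in_g1 = rng.random(n_events) < g1_fraction
    dna = np.empty(n_events)
    dna[in_g1] = dna_2n * _lognormal_factors(rng, dna_cv, int(in_g1.sum()))
    n_sg2 = int((~in_g1).sum())
    dna[~in_g1] = (
        dna_2n * (1.0 + rng.random(n_sg2)) * _lognormal_factors(rng, dna_cv, n_sg2)
    )

    cov = [[1.0, correlation], [correlation, 1.0]]
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_events, method="svd")
    sox2 = level_scale * np.exp(config.log_sd * z[:, 0])
    oct4 = level_scale * np.exp(config.log_sd * z[:, 1])
    sox2 = sox2 * _lognormal_factors(rng, config.obs_cv, n_events)
    oct4 = oct4 * _lognormal_factors(rng, config.obs_cv, n_events)
    return pd.DataFrame(
        {"sox2_level": sox2, "oct4_level": oct4, "dna_content": dna, "g1_truth": in_g1}
    )


def make_calibration_frames(
    config: GeneratorConfig,
    n_cells: int,
    *,
    molecules_mean: float = 1000.0,
    molecules_cv: float = 0.3,
    seed: int | None = None,
) -> CalibrationSet:
    """Generate calibration cells carrying a 1:1 NLUC-FLUC fusion.

    Each cell holds ``M`` fusion molecules; NLUC intensity is
    ``kappa * M`` and FLUC intensity ``phi_f * M``, each with independent
    mean-one lognormal measurement noise.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    rng = _rng(config, seed)
    molecules = molecules_mean * _lognormal_factors(rng, molecules_cv, n_cells)
    nluc = config.kappa * molecules * _lognormal_factors(rng, config.obs_cv, n_cells)
    fluc = config.phi_f * molecules * _lognormal_factors(rng, config.obs_cv, n_cells)
    data = pd.DataFrame({"nluc_intensity": nluc, "fluc_intensity": fluc})
    return CalibrationSet(data, phi_f=config.phi_f)


# generate_* aliases for callers preferring the verb form
generate_fluctuation_traces = make_fluctuation_traces
generate_decay_traces = make_decay_traces
generate_commitment_traces = make_commitment_traces
generate_snapshot_population = make_snapshot_population
generate_calibration_frames = make_calibration_frames
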