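"""In-silico flow-cytometry gating and the post-sort mean-reversion readout.

DNA-content gating fits a two-component model to log DNA content -- a
Gaussian 2N peak (G1 cells) plus a blurred-uniform 2N-4N continuum (S/G2)
-- by EM; G1 is the peak-posterior region within +/-2 SD of the 2N peak,
S the continuum-posterior region between the G1 upper bound and 1.9x the
peak position.  Manual bounds can override the model fit.

Expression windows are defined on empirical quantiles with a deterministic
tie rule (stable sort, lower index first): an intermediate f-band keeps
the central fraction f, top/bottom windows the outer fraction f, and the
four corner windows (SHOH/SHOL/SLOH/SLOL) are solved numerically on the
empirical joint distribution so that each corner captures a target
fraction of all events.

``mean_reversion_experiment`` simulates the sort-and-recover protocol: a
population is gated into high/low windows, each sorted cell's latent
log-level is propagated forward under the mean-reverting dynamics, and
the shrinkage of the sorted-group deviations toward the mean is reported
together with a one-sided Welch p-value for the remaining high-vs-low
difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig
from .containers import validate_snapshot

__all__ = [
    "GateSpec",
    "DnaMixtureFit",
    "gate_dna_phase",
    "quantile_window",
    "corner_windows",
    "ReversionReport",
    "mean_reversion_experiment",
]


@dataclass
class GateSpec:
    """Quantile-based gate description.

    ``phase`` restricts to a DNA-content phase; ``window`` is one of
    "intermediate", "top", "bottom" with fraction ``frac``; ``channel``
    names the gated measurement column.
    """

    phase: str = "any"  # "G1", "S" or "any"
    window: str = "top"
    frac: float = 0.3
    channel: str = "sox2_level"

    def __post_init__(self) -> None:
        if self.phase not in ("G1", "S", "any"):
            raise ValueError(f"invalid phase {self.phase!r}")
        if self.window not in ("intermediate", "top", "bottom"):
            raise ValueError(f"invalid window {self.window!r}")
        if not (0.0 < self.frac < 1.0):
            raise ValueError("frac must be in (0, 1)")


@dataclass
class DnaMixtureFit:
    mu: float  # log 2N peak position
    sd: float
    weight_g1: float
    n_iter: int


def _fit_dna_mixture(x: np.ndarray, max_iter: int = 500, tol: float = 1e-8) -> DnaMixtureFit:
    """EM for log-DNA: w * N(mu, sd^2) + (1-w) * blurred Uniform[mu, mu+ln2]."""
    mu = float(np.percentile(x, 25))
    sd = max(1.4826 * np.median(np.abs(x - mu)), 1e-3)
    w = 0.5
    span = math.log(2.0)
    ll_old = -np.inf
    for it in range(max_iter):
        peak = w * stats.norm.pdf(x, mu, sd)
        # uniform on [mu, mu+ln2] convolved with the measurement Gaussian
        cont = (1.0 - w) * (
            (stats.norm.cdf((x - mu) / sd) - stats.norm.cdf((x - mu - span) / sd)) / span
        )
        total = peak + cont + 1e-300
        resp = peak / total
        w = float(resp.mean())
        sw = resp.sum()
        if sw < 10:
            raise ValueError(
                "DNA-content model degenerate (no 2N peak); pass manual_bounds"
            )
        mu = float((resp * x).sum() / sw)
        sd = float(math.sqrt(max((resp * (x - mu) ** 2).sum() / sw, 1e-10)))
        ll = float(np.log(total).sum())
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    if sd > 0.5 * span:
        raise ValueError(
            "DNA-content model degenerate (peak as wide as the S/G2 span); "
            "pass manual_bounds"
        )
    return DnaMixtureFit(mu, sd, w, it + 1)


def gate_dna_phase(
    snapshot: pd.DataFrame,
    phase: str,
    manual_bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boolean mask of events in the requested DNA-content phase.

    With ``manual_bounds=(lo, hi)`` the mask is a plain interval test on
    raw DNA content.  Otherwise the two-component model is fitted and G1
    is the peak-assigned region within +/-2 SD of the 2N peak, S the
    continuum-assigned region up to 1.9x the peak position.
    """
    validate_snapshot(snapshot, require_levels=False)
    dna = snapshot["dna_content"].to_numpy(float)
    if phase == "any":
        return np.ones(len(dna), dtype=bool)
    if phase not in ("G1", "S"):
        raise ValueError(f"invalid phase {phase!r}")
    if manual_bounds is not None:
        lo, hi = manual_bounds
        return (dna >= lo) & (dna <= hi)
    x = np.log(dna)
    fit = _fit_dna_mixture(x)
    peak = fit.weight_g1 * stats.norm.pdf(x, fit.mu, fit.sd)
    span = math.log(2.0)
    cont = (1.0 - fit.weight_g1) * (
        (stats.norm.cdf((x - fit.mu) / fit.sd) - stats.norm.cdf((x - fit.mu - span) / fit.sd))
        / span
    )
    peak_assigned = peak >= cont
    g1_band = np.abs(x - fit.mu) <= 2.0 * fit.sd
    if phase == "G1":
        return peak_assigned & g1_band
    s_band = (x > fit.mu + 2.0 * fit.sd) & (x <= fit.mu + math.log(1.9))
    return (~peak_assigned) & s_band


def quantile_window(values, spec: GateSpec) -> np.ndarray:
    """Boolean mask selecting the spec's empirical-quantile window.

    Selection is rank-based (stable sort; ties broken by lower original
    index first), so on n distinct values an f-window selects exactly
    round(f * n) events.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 10:
        raise ValueError("need >= 10 events for quantile gating")
    order = np.argsort(values, kind="stable")
    position = np.empty(n, dtype=int)
    position[order] = np.arange(n)
    count = int(round(spec.frac * n))
    if count < 1:
        raise ValueError("window selects no events")
    if spec.window == "top":
        mask = position >= n - count
    elif spec.window == "bottom":
        mask = position < count
    else:  # intermediate
        lo = int(math.floor((0.5 - spec.frac / 2.0) * n))
        mask = (position >= lo) & (position < lo + count)
    return mask


def _corner_fraction(sox2, oct4, q, sox_high: bool, oct_high: bool) -> np.ndarray:
    s_thr = np.quantile(sox2, 1 - q if sox_high else q)
    o_thr = np.quantile(oct4, 1 - q if oct_high else q)
    s_mask = sox2 >= s_thr if sox_high else sox2 <= s_thr
    o_mask = oct4 >= o_thr if oct_high else oct4 <= o_thr
    return s_mask & o_mask


def corner_windows(
    snapshot: pd.DataFrame, frac: float = 0.2, tol: float = 1e-4
) -> dict[str, np.ndarray]:
    """Solve the four SOX2/OCT4 corner windows, each capturing ``frac``.

    For every corner the symmetric outer tail fraction q (same for both
    channels) is solved by bisection on the empirical joint distribution
    so that the corner intersection captures ``frac`` of all events.
    q is capped at 0.5, keeping the four masks disjoint; if even q = 0.5
    cannot reach the target (strong dependence), an error advises a lower
    ``frac``.
    """
    if frac * 4 > 1:
        raise ValueError("frac * 4 must not exceed 1")
    validate_snapshot(snapshot)
    sox2 = snapshot["sox2_level"].to_numpy(float)
    oct4 = snapshot["oct4_level"].to_numpy(float)
    corners = {
        "SHOH": (True, True),
        "SHOL": (True, False),
        "SLOH": (False, True),
        "SLOL": (False, False),
    }
    masks: dict[str, np.ndarray] = {}
    for name, (s_high, o_high) in corners.items():
        hi = 0.5
        if _corner_fraction(sox2, oct4, hi, s_high, o_high).mean() < frac - tol:
            raise ValueError(
                f"corner {name} cannot capture {frac:.0%} of events under the "
                "observed channel dependence; lower frac"
            )
        lo = 0.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            got = _corner_fraction(sox2, oct4, mid, s_high, o_high).mean()
            if got < frac:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-12:
                break
        masks[name] = _corner_fraction(sox2, oct4, hi, s_high, o_high)
    return masks


@dataclass
class ReversionReport:
    """Post-sort mean-reversion summary (log-level deviations from the mean)."""

    delta_t_h: float
    relax_time_h: float
    latent_dev_high_0: float
    latent_dev_low_0: float
    latent_dev_high_dt: float
    latent_dev_low_dt: float
    latent_shrinkage: float  # separation(dt) / separation(0) on latent levels
    observed_shrinkage: float  # same on freshly observed levels
    pvalue_high_vs_low_dt: float  # one-sided Welch on observed levels at dt
    n_high: int
    n_low: int

    @property
    def change_high(self) -> float:
        return self.latent_dev_high_dt - self.latent_dev_high_0

    @property
    def change_low(self) -> float:
        return self.latent_dev_low_dt - self.latent_dev_low_0


def mean_reversion_experiment(
    config: GeneratorConfig,
    gate: GateSpec | None = None,
    delta_t_h: float = 8.0,
    n_events: int = 20000,
    seed: int | None = None,
) -> ReversionReport:
    """Sort high/low expression windows and follow their reversion to the mean.

    Latent log-levels start at stationarity (N(0, log_sd^2)); the sort is
    applied to a noisy observation; the latent level is then propagated
    ``delta_t_h`` forward under the mean-reverting dynamics
    (x -> x e^(-dt/tau) + stationary innovation).  Group deviations are
    reported on the latent levels and on fresh observations (the sorted
    population is re-measured, as in a post-sort flow analysis, so the
    selection bias of the sort signal does not enter the baseline).
    With ``delta_t_h = 0`` the report shows exactly zero change.
    """
    gate = gate or GateSpec(window="top", frac=0.3)
    if not (gate.frac > 0):
        raise ValueError("gate frac must be positive")
    if config.relax_time_h is None:
        raise ValueError("propagation requires the dynamics (relax_time_h) in config")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    x0 = rng.normal(0.0, config.log_sd, n_events)
    obs_noise_sd = math.sqrt(math.log1p(config.obs_cv**2))
    sort_obs = x0 + rng.normal(0.0, obs_noise_sd, n_events)

    high = quantile_window(sort_obs, GateSpec(window="top", frac=gate.frac))
    low = quantile_window(sort_obs, GateSpec(window="bottom", frac=gate.frac))
    if high.sum() < 50 or low.sum() < 50:
        raise ValueError("gate selects fewer than 50 events")

    if math.isinf(config.relax_time_h):
        a = 1.0
    else:
        a = math.exp(-delta_t_h / config.relax_time_h)
    innov_sd = config.log_sd * math.sqrt(max(0.0, 1.0 - a * a))
    x_dt = a * x0 + rng.normal(0.0, innov_sd, n_events) if delta_t_h > 0 else x0

    obs_0 = x0 + rng.normal(0.0, obs_noise_sd, n_events)  # fresh post-sort baseline
    obs_dt = x_dt + rng.normal(0.0, obs_noise_sd, n_events) if delta_t_h > 0 else obs_0

    lat_h0, lat_l0 = float(x0[high].mean()), float(x0[low].mean())
    lat_hdt, lat_ldt = float(x_dt[high].mean()), float(x_dt[low].mean())
    latent_shrink = (lat_hdt - lat_ldt) / (lat_h0 - lat_l0)
    obs_shrink = float(
        (obs_dt[high].mean() - obs_dt[low].mean()) / (obs_0[high].mean() - obs_0[low].mean())
    )
    welch = stats.ttest_ind(
        obs_dt[high], obs_dt[low], equal_var=False, alternative="greater"
    )
    return ReversionReport(
        delta_t_h=delta_t_h,
        relax_time_h=config.relax_time_h,
        latent_dev_high_0=lat_h0,
        latent_dev_low_0=lat_l0,
        latent_dev_high_dt=lat_hdt,
        latent_dev_low_dt=lat_ldt,
        latent_shrinkage=float(latent_shrink),
        observed_shrinkage=obs_shrink,
        pvalue_high_vs_low_dt=float(welch.pvalue),
        n_high=int(high.sum()),
        n_low=int(low.sum()),
    )
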