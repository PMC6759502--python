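"""Configuration objects for the simulation and analysis pipeline.

``GeneratorConfig`` collects every tunable of the synthetic trace generator:
cell-cycle timing, the stationary spread and relaxation time of the
mean-reverting log-concentration process, the nuclear-volume model anchor,
measurement noise, and the intensity calibration constants.  All stages of
the pipeline read their defaults from here, and configurations round-trip
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["GeneratorConfig", "PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic single-cell trace generator.

    Parameters
    ----------
    cycle_mean_h, cycle_sd_h
        Mean and SD of the cell-cycle duration (hours).  Durations are drawn
        from a normal truncated below at ``0.5 * cycle_mean_h`` and rounded
        to a whole number of sampling frames.
    log_sd
        Stationary standard deviation of log-concentration (dimensionless).
        Controls the fluctuation amplitude; 0.3 yields a median 2-3-fold
        per-cell concentration range over two cycles.
    relax_time_h
        Relaxation (mean-reversion) time of the log-concentration process,
        which sets the mixing time; defaults to one mean cell cycle.
    v0_fl
        Nuclear volume at cycle start (femtolitres).  The nuclear volume
        grows linearly to ``2 * v0_fl`` at division.
    base_conc_nm
        Stationary mean nuclear concentration (nM).
    obs_cv
        Coefficient of variation of the multiplicative (lognormal,
        mean-one) measurement noise.  0 disables noise entirely.
    kappa
        Detection constant: intensity units recorded per molecule.
    phi_f
        FLUC detection constant (intensity units per FLUC molecule), used
        by the calibration-frame generator.
    bg_level
        Additive background level (intensity units) recorded alongside the
        signal.
    interval_h
        Sampling interval (hours); 0.25 h mirrors 15-min time-lapse frames.
    seed
        Seed for the generator's random stream.  Identical seeds give
        bit-identical output.
    """

    cycle_mean_h: float = 13.0
    cycle_sd_h: float = 1.5
    log_sd: float = 0.3
    relax_time_h: float = 13.0
    v0_fl: float = 500.0
    base_conc_nm: float = 150.0
    obs_cv: float = 0.1
    kappa: float = 4.0
    phi_f: float = 2.0
    bg_level: float = 50.0
    interval_h: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "cycle_mean_h",
            "cycle_sd_h",
            "relax_time_h",
            "v0_fl",
            "base_conc_nm",
            "kappa",
            "phi_f",
            "interval_h",
        ]
        for name in positive:
            value = getattr(self, name)
            if not (value > 0):
                raise ConfigError(f"{name} must be strictly positive, got {value!r}")
        for name in ("log_sd", "obs_cv", "bg_level"):
            value = getattr(self, name)
            if not (value >= 0) or not math.isfinite(value):
                raise ConfigError(f"{name} must be finite and >= 0, got {value!r}")
        if self.interval_h >= self.cycle_mean_h:
            raise ConfigError("interval_h must be shorter than the mean cycle")
        if not isinstance(self.seed, (int,)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    def replace(self, **kwargs: Any) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(payload)


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration: stage parameters plus plumbing."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    grid_size: int = 100
    n_boot: int = 1000
    mixing_threshold: float = 1.0 / math.e
    fate_threshold: float = 500.0
    fate_min_hours: float = 4.0
    fdr: float = 0.1
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        payload = dataclasses.asdict(self)
        return payload

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PipelineConfig":
        payload = dict(payload)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "generator" in payload and isinstance(payload["generator"], dict):
            payload["generator"] = GeneratorConfig.from_dict(payload["generator"])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(payload)
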