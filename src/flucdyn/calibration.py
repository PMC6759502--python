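"""Absolute calibration of luminescence intensities to molecule numbers.

Calibration cells express a 1:1 NLUC-FLUC fusion, so their FLUC intensity
divided by the known FLUC detection constant ``phi_f`` gives the molecule
count of the fusion, and their NLUC intensity divided by that count gives
the per-molecule NLUC detection constant ``kappa``.  The per-cell kappa
estimates are summarized by their median (robust to occasional corrupted
calibration cells); sample traces are converted with
``molecules = (intensity - background) / kappa_hat``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .containers import CalibrationSet, TraceSet

__all__ = ["ConversionModel", "MoleculeCalibrator", "fit_conversion_factor", "to_molecules"]


@dataclass
class ConversionModel:
    """Fitted intensity-per-molecule conversion factor."""

    kappa_hat: float
    n_cells_used: int
    dispersion: float  # median absolute deviation of per-cell kappa estimates

    def __post_init__(self) -> None:
        if not (self.kappa_hat > 0):
            raise ValueError(f"kappa_hat must be > 0, got {self.kappa_hat!r}")
        if self.n_cells_used < 1:
            raise ValueError("n_cells_used must be >= 1")


class MoleculeCalibrator(BaseEstimator):
    """Estimator converting intensities to absolute molecule numbers.

    ``fit`` consumes a :class:`CalibrationSet`; ``transform`` rewrites a
    :class:`TraceSet`'s intensities as background-subtracted molecule
    counts (negatives clipped to zero, count kept in ``n_clipped_``).

    Attributes
    ----------
    kappa_hat_ : float
        Median per-cell intensity-per-molecule estimate.
    dispersion_ : float
        Median absolute deviation of the per-cell estimates.
    n_cells_used_ : int
        Calibration cells entering the median (non-positive FLUC excluded).
    """

    def __init__(self, phi_f: float | None = None):
        self.phi_f = phi_f

    def fit(self, cal: CalibrationSet, y=None) -> "MoleculeCalibrator":
        phi_f = self.phi_f if self.phi_f is not None else cal.phi_f
        if not (phi_f > 0):
            raise ValueError("phi_f must be known and > 0")
        if len(cal) == 0:
            raise ValueError("calibration set is empty")
        nluc = cal.data["nluc_intensity"].to_numpy(float)
        fluc = cal.data["fluc_intensity"].to_numpy(float)
        ok = fluc > 0
        n_excluded = int((~ok).sum())
        if n_excluded:
            warnings.warn(
                f"excluded {n_excluded} calibration cells with non-positive "
                "FLUC intensity",
                stacklevel=2,
            )
        if not ok.any():
            raise ValueError("all calibration cells have non-positive FLUC intensity")
        molecules = fluc[ok] / phi_f
        kappa_i = nluc[ok] / molecules
        self.kappa_per_cell_ = kappa_i
        self.kappa_hat_ = float(np.median(kappa_i))
        self.dispersion_ = float(np.median(np.abs(kappa_i - self.kappa_hat_)))
        self.n_cells_used_ = int(ok.sum())
        self.n_excluded_ = n_excluded
        if not (self.kappa_hat_ > 0):
            raise ValueError("fitted kappa_hat is non-positive")
        return self

    @property
    def model_(self) -> ConversionModel:
        return ConversionModel(self.kappa_hat_, self.n_cells_used_, self.dispersion_)

    def transform(self, traces: TraceSet) -> TraceSet:
        if not hasattr(self, "kappa_hat_"):
            raise ValueError("MoleculeCalibrator is not fitted")
        return _convert(traces, self.kappa_hat_, self)


def _convert(traces: TraceSet, kappa_hat: float, owner=None) -> TraceSet:
    if not (kappa_hat > 0):
        raise ValueError(f"kappa_hat must be > 0, got {kappa_hat!r}")
    out = traces.copy()
    values = (
        out.data["intensity"].to_numpy(float) - out.data["background"].to_numpy(float)
    ) / kappa_hat
    n_clipped = int((values < 0).sum())
    values = np.clip(values, 0.0, None)
    out.data["intensity"] = values
    out.data["background"] = 0.0
    out.units = {ch: "molecules" for ch in out.channels()}
    if owner is not None:
        owner.n_clipped_ = n_clipped
    return out


def fit_conversion_factor(cal: CalibrationSet, phi_f: float | None = None) -> ConversionModel:
    """Fit the intensity-per-molecule conversion factor from calibration cells."""
    return MoleculeCalibrator(phi_f=phi_f).fit(cal).model_


def to_molecules(traces: TraceSet, model: ConversionModel) -> TraceSet:
    """Convert background-subtracted intensities to molecule numbers."""
    return _convert(traces, model.kappa_hat)
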