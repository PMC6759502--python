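"""Differential-accessibility region grouping and interval overlap.

Regions tested in three contrasts -- O (OCT4-high vs OCT4-low),
S (SOX2-high vs SOX2-low) and C (SHOH vs SLOL) -- are grouped by which
contrasts reach significance (adjusted p below an FDR threshold, default
0.1) and by fold-change direction:

* significant in O only  -> OCT4-regulated (sign of logFC_O)
* significant in S only  -> SOX2-regulated (sign of logFC_S)
* significant in both O and S, or in C at all -> co-regulated
  (sign of logFC_C when C is significant; otherwise the concordant O/S
  sign, falling back to the larger |logFC| when they disagree)
* no significant contrast -> Unaffected.

Interval overlap uses 0-based half-open coordinates: a region overlaps a
feature set when it shares at least one base with any feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr
from sklearn.base import BaseEstimator

__all__ = [
    "GROUP_NAMES",
    "RegionGrouper",
    "assign_region_groups",
    "overlap_fraction",
]

CONTRASTS = ("O", "S", "C")
REQUIRED_COLUMNS = [f"logFC_{c}" for c in CONTRASTS] + [f"padj_{c}" for c in CONTRASTS]

GROUP_NAMES = (
    "Upregulated OCT4",
    "Downregulated OCT4",
    "Upregulated SOX2",
    "Downregulated SOX2",
    "Upregulated OCT4&SOX2",
    "Downregulated OCT4&SOX2",
    "Unaffected",
)


class RegionGrouper(BaseEstimator):
    """Assign each region to one of the six regulated groups or Unaffected.

    Parameters
    ----------
    fdr : float
        Adjusted-p significance threshold (at least one contrast below it
        makes a region non-Unaffected).
    discordant_policy : str
        Direction rule for co-regulated regions whose defining contrasts
        disagree in sign and C is not significant: ``"larger_logfc"``
        (default) uses the larger |logFC| of O/S; ``"contrast_c"`` always
        falls back to C's sign.
    """

    def __init__(self, fdr: float = 0.1, discordant_policy: str = "larger_logfc"):
        self.fdr = fdr
        self.discordant_policy = discordant_policy

    def fit(self, table: pd.DataFrame, y=None) -> "RegionGrouper":
        self.groups_ = self.predict(table)
        self.counts_ = self.groups_.value_counts().reindex(GROUP_NAMES, fill_value=0)
        return self

    def predict(self, table: pd.DataFrame) -> pd.Series:
        if self.discordant_policy not in ("larger_logfc", "contrast_c"):
            raise ValueError(f"unknown discordant_policy {self.discordant_policy!r}")
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"missing column: {missing[0]}")
        padj = {c: table[f"padj_{c}"].to_numpy(float) for c in CONTRASTS}
        lfc = {c: table[f"logFC_{c}"].to_numpy(float) for c in CONTRASTS}
        for c in CONTRASTS:
            p = padj[c]
            if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
                raise ValueError(f"padj_{c} outside [0, 1]")
        sig = {c: padj[c] < self.fdr for c in CONTRASTS}

        n = len(table)
        labels = np.full(n, "Unaffected", dtype=object)
        co = (sig["O"] & sig["S"]) | sig["C"]
        oct4_only = sig["O"] & ~sig["S"] & ~sig["C"]
        sox2_only = sig["S"] & ~sig["O"] & ~sig["C"]

        def name(prefix: np.ndarray, target: str) -> np.ndarray:
            return np.where(prefix, f"Upregulated {target}", f"Downregulated {target}")

        labels[oct4_only] = name(lfc["O"] > 0, "OCT4")[oct4_only]
        labels[sox2_only] = name(lfc["S"] > 0, "SOX2")[sox2_only]

        # direction of co-regulated regions
        up_c = lfc["C"] > 0
        concordant = np.sign(lfc["O"]) == np.sign(lfc["S"])
        if self.discordant_policy == "larger_logfc":
            fallback_up = np.where(
                concordant,
                lfc["O"] > 0,
                np.where(np.abs(lfc["O"]) >= np.abs(lfc["S"]), lfc["O"] > 0, lfc["S"] > 0),
            )
        else:
            fallback_up = np.where(concordant, lfc["O"] > 0, up_c)
        co_up = np.where(sig["C"], up_c, fallback_up)
        labels[co] = name(co_up, "OCT4&SOX2")[co]
        return pd.Series(labels, index=table.index, name="group")


def assign_region_groups(
    table: pd.DataFrame, fdr: float = 0.1, discordant_policy: str = "larger_logfc"
) -> pd.Series:
    """Group regions by contrast significance pattern and fold-change sign."""
    return RegionGrouper(fdr=fdr, discordant_policy=discordant_policy).predict(table)


def _as_pyranges(df: pd.DataFrame, what: str) -> pr.PyRanges:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{what}: missing column: {col}")
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    bad = np.nonzero(~(start < end))[0]
    if bad.size:
        raise ValueError(f"{what}: malformed interval at row {bad[0]} (start >= end)")
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": df["chrom"].astype(str).to_numpy(),
                "Start": start.astype(np.int64),
                "End": end.astype(np.int64),
                "_row": np.arange(len(df)),
            }
        )
    )


def overlap_fraction(
    regions: pd.DataFrame,
    features: pd.DataFrame,
    groups: pd.Series | None = None,
    assembly: str | None = None,
    feature_assembly: str | None = None,
) -> pd.Series:
    """Fraction of regions (per group) sharing >= 1 bp with any feature.

    Coordinates are 0-based half-open; both tables need chrom/start/end
    columns.  When ``groups`` is None a single overall fraction is
    returned under the name "all".
    """
    if assembly is not None and feature_assembly is not None and assembly != feature_assembly:
        raise ValueError(f"assembly mismatch: {assembly!r} vs {feature_assembly!r}")
    r = _as_pyranges(regions, "regions")
    f = _as_pyranges(features, "features")
    counts = r.count_overlaps(f).df.sort_values("_row")["NumberOverlaps"].to_numpy()
    hit = counts > 0
    if groups is None:
        return pd.Series({"all": float(hit.mean())}, name="overlap_fraction")
    groups = np.asarray(groups)
    if len(groups) != len(regions):
        raise ValueError("groups must align with regions")
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        out[g] = float(hit[sel].mean())
    return pd.Series(out, name="overlap_fraction")
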