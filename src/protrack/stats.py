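"""Growth and proliferation statistics over tracked lineages.

Implements the population-level quantities: per-lineage growth rate
g = area_k / area_0, the response ratio n = n_>1 / n_<1 separating
expanding from shrinking cells, per-interval relative area changes,
fixed-width area histograms, the equivalent radius sqrt(A/pi) used to
summarize area distributions, and the microcalli proliferation-rate
estimator based on a pixel-area threshold (default 4000 px).

All quantities are dimensionless ratios of areas, so they are invariant
to the pixel calibration: g computed from um^2 equals g computed from
px^2 to machine precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResponseSummary",
    "ProliferationResult",
    "growth_rates",
    "response_ratio",
    "interval_changes",
    "area_histogram",
    "histogram_overlay",
    "equivalent_radius",
    "proliferation_rate",
]

MICROCALLI_THRESHOLD_PX = 4000


@dataclass(frozen=True)
class ResponseSummary:
    """Counts of expanding / shrinking lineages and their ratio n.

    Lineages with g exactly 1 are reported in ``n_eq1`` and excluded from
    the ratio; ``n`` is None when no lineage shrank (ratio undefined).
    """

    n_gt1: int
    n_lt1: int
    n_eq1: int
    n: float | None


@dataclass(frozen=True)
class ProliferationResult:
    """Background-normalized count of objects above the microcalli threshold."""

    n_large_late: int
    n_large_early: int
    n_cells_early: int
    relative_rate: float


def growth_rates(lineage_tbl: pd.DataFrame, target_dai: int, area_col: str = "area_um2") -> pd.DataFrame:
    """Per-lineage growth rate g = area at DAI ``target_dai`` over area at DAI0.

    Only lineages tracked through the target DAI contribute.  Returns a
    frame with lineage_id, area_0, area_k and g.
    """
    if target_dai < 1:
        raise ValueError("target_dai must be >= 1")
    piv = lineage_tbl.pivot_table(index="lineage_id", columns="timepoint", values=area_col)
    if 0 not in piv.columns:
        raise ValueError("lineage table holds no DAI0 records")
    if target_dai not in piv.columns:
        return pd.DataFrame(columns=["lineage_id", "area_0", "area_k", "g"])
    sel = piv[[0, target_dai]].dropna()
    if (sel[0] <= 0).any():
        raise ValueError("area at DAI0 must be positive")
    return pd.DataFrame(
        {
            "lineage_id": sel.index.to_numpy(),
            "area_0": sel[0].to_numpy(),
            "area_k": sel[target_dai].to_numpy(),
            "g": (sel[target_dai] / sel[0]).to_numpy(),
        }
    )


def response_ratio(g: pd.DataFrame | np.ndarray) -> ResponseSummary:
    """Response ratio n = (# lineages with g > 1) / (# with g < 1).

    Counts use strict inequalities; g exactly 1 is counted separately and
    enters neither side of the ratio.
    """
    vals = np.asarray(g["g"] if isinstance(g, pd.DataFrame) else g, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one growth rate")
    n_gt1 = int((vals > 1.0).sum())
    n_lt1 = int((vals < 1.0).sum())
    n_eq1 = int((vals == 1.0).sum())
    n = (n_gt1 / n_lt1) if n_lt1 > 0 else None
    return ResponseSummary(n_gt1=n_gt1, n_lt1=n_lt1, n_eq1=n_eq1, n=n)


def interval_changes(lineage_tbl: pd.DataFrame, area_col: str = "area_um2") -> pd.DataFrame:
    """Relative area change (a_{k+1} - a_k)/a_k per consecutive tracked interval.

    Returns one row per lineage per consecutive DAI pair present in the
    lineage, with columns lineage_id, well, dai_from, dai_to, rel_change.
    """
    rows = []
    for lid, grp in lineage_tbl.sort_values("timepoint").groupby("lineage_id"):
        tps = grp["timepoint"].to_numpy()
        areas = grp[area_col].to_numpy(dtype=float)
        well = grp["well"].iloc[0] if "well" in grp else ""
        for k in range(len(tps) - 1):
            if tps[k + 1] == tps[k] + 1:
                if areas[k] <= 0:
                    raise ValueError("areas must be positive")
                rows.append((lid, well, int(tps[k]), int(tps[k + 1]), (areas[k + 1] - areas[k]) / areas[k]))
    return pd.DataFrame(rows, columns=["lineage_id", "well", "dai_from", "dai_to", "rel_change"])


def area_histogram(areas, bin_width: float = 100.0, origin: float = 0.0) -> pd.DataFrame:
    """Counts over half-open fixed-width bins [lo, lo + w).

    Total count always equals the number of input records.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = np.asarray(areas, dtype=float)
    if vals.size == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
    idx = np.floor((vals - origin) / bin_width).astype(int)
    lo_idx, hi_idx = idx.min(), idx.max()
    counts = np.bincount(idx - lo_idx, minlength=hi_idx - lo_idx + 1)
    lo = origin + np.arange(lo_idx, hi_idx + 1) * bin_width
    return pd.DataFrame({"bin_lo": lo, "bin_hi": lo + bin_width, "count": counts})


def histogram_overlay(areas_a, areas_b, bin_width: float = 100.0, origin: float = 0.0) -> pd.DataFrame:
    """Two aligned histograms for overlay plots (e.g. DAI1 vs DAI3 tracked cells)."""
    ha = area_histogram(areas_a, bin_width, origin).set_index("bin_lo")
    hb = area_histogram(areas_b, bin_width, origin).set_index("bin_lo")
    merged = ha[["count"]].join(hb[["count"]], how="outer", lsuffix="_a", rsuffix="_b").fillna(0)
    merged = merged.rename(columns={"count_a": "count_a", "count_b": "count_b"}).sort_index()
    merged["bin_hi"] = merged.index + bin_width
    return merged.reset_index()[["bin_lo", "bin_hi", "count_a", "count_b"]].astype(
        {"count_a": int, "count_b": int}
    )


def equivalent_radius(area_um2):
    """Equivalent radius sqrt(A/pi) in um for a given area in um^2.

    This is the numeric convention used to summarize protoplast area
    distributions (e.g. 850 um^2 -> 16.45 um); note it is the radius of
    the equivalent disk, not twice it.
    """
    arr = np.asarray(area_um2, dtype=float)
    if np.any(arr < 0):
        raise ValueError("area must be non-negative")
    out = np.sqrt(arr / math.pi)
    return float(out) if np.isscalar(area_um2) or arr.ndim == 0 else out


def _object_sizes(labels: np.ndarray) -> np.ndarray:
    counts = np.bincount(np.asarray(labels).ravel())
    sizes = counts[1:]
    return sizes[sizes > 0]


def proliferation_rate(
    labels_late: np.ndarray,
    labels_early: np.ndarray,
    threshold_px: int = MICROCALLI_THRESHOLD_PX,
) -> ProliferationResult:
    """Relative proliferation rate from early (DAI1) and late label maps.

    Objects larger than ``threshold_px`` are proliferating microcalli; the
    early frame defines both the background count of already-large objects
    and the reference cell number:
    ``rate = (n_large_late - n_large_early) / (n_cells_early - n_large_early)``.
    A negative numerator is clamped to 0 with a warning.
    """
    if threshold_px <= 0:
        raise ValueError("threshold_px must be positive")
    sizes_late = _object_sizes(labels_late)
    sizes_early = _object_sizes(labels_early)
    n_large_late = int((sizes_late > threshold_px).sum())
    n_large_early = int((sizes_early > threshold_px).sum())
    n_cells_early = int(sizes_early.size)
    denom = n_cells_early - n_large_early
    if denom <= 0:
        raise ValueError("early frame has no objects below the microcalli threshold")
    num = n_large_late - n_large_early
    if num < 0:
        warnings.warn("fewer large objects late than early; clamping proliferation rate to 0")
        num = 0
    return ProliferationResult(
        n_large_late=n_large_late,
        n_large_early=n_large_early,
        n_cells_early=n_cells_early,
        relative_rate=num / denom,
    )
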