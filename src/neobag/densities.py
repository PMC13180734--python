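"""Inter-breath-interval probability densities over development.

Each recording's IBIs are binned at 0.1-s resolution up to 50 s (longer
IBIs are removed) and scaled to unit area.  Recording densities are then
pooled into densities conditional on PMA or brain-age gap: each
recording receives a Gaussian weight in the distance (in days) between
its own PMA/gap and the grid point -- full width at half maximum 13
days, hard zero beyond 14 days -- and the conditional density is the
per-bin *weighted median* of the recording densities, renormalised to
unit area.  The weighted median (rather than a weighted mean) is robust
to individual outlier recordings.

Weighted-median convention: the smallest value whose cumulative
normalised weight reaches 0.5 (the lower weighted median).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BIN_WIDTH_S = 0.1
MAX_IBI_S = 50.0
FWHM_DAYS = 13.0
CUTOFF_DAYS = 14.0
#: grid step along the conditioning axis, in weeks (1 day)
GRID_STEP_WEEKS = 1.0 / 7.0

PMA_RANGE_WEEKS = (31.0, 36.0)
GAP_RANGE_WEEKS = (-3.0, 3.0)


@dataclass(frozen=True)
class RecordingDensity:
    """Unit-area IBI density of one recording on the fixed 0.1-s grid."""

    bin_edges: np.ndarray      # seconds, len = n_bins + 1
    density: np.ndarray        # 1/s, len = n_bins

    def __post_init__(self):
        area = float(np.sum(self.density) * BIN_WIDTH_S)
        if abs(area - 1.0) > 1e-9:
            raise ValueError(f"density must integrate to 1, got {area}")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")


@dataclass(frozen=True)
class DensityGrid:
    """IBI densities conditioned on PMA or brain-age gap."""

    axis: str                   # 'pma' or 'gap'
    axis_values: np.ndarray     # weeks
    bin_edges: np.ndarray       # seconds
    densities: np.ndarray       # (n_grid, n_bins), NaN rows where empty
    cumulative: np.ndarray      # (n_grid, n_bins)
    empty: np.ndarray           # (n_grid,) bool

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (axis_value, bin_left_s, density, cumulative)."""
        left = self.bin_edges[:-1]
        rows = []
        for v, d, c, e in zip(self.axis_values, self.densities,
                              self.cumulative, self.empty):
            if e:
                continue
            rows.append(pd.DataFrame({"axis_value": v, "bin_left_s": left,
                                      "density": d, "cumulative": c}))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["axis_value", "bin_left_s", "density", "cumulative"])


def ibi_bin_edges() -> np.ndarray:
    n_bins = int(round(MAX_IBI_S / BIN_WIDTH_S))
    return np.linspace(0.0, MAX_IBI_S, n_bins + 1)


def recording_density(intervals) -> RecordingDensity:
    """Unit-area histogram of one recording's IBIs (0.1-s bins, <= 50 s)."""
    x = np.asarray(intervals, dtype=float)
    x = x[x <= MAX_IBI_S]
    if x.size == 0:
        raise ValueError("no inter-breath intervals at or below 50 s")
    edges = ibi_bin_edges()
    counts, _ = np.histogram(x, bins=edges)
    density = counts / (counts.sum() * BIN_WIDTH_S)
    return RecordingDensity(bin_edges=edges, density=density)


def gaussian_weights(distance_days, fwhm_days: float = FWHM_DAYS,
                     cutoff_days: float = CUTOFF_DAYS) -> np.ndarray:
    """Gaussian distance weights with a hard cutoff.

    exp(-d^2 / (2 sigma^2)) with sigma = FWHM / (2 sqrt(2 ln 2)); a
    distance of half the FWHM weighs exactly 0.5, and weights are set to
    0 beyond the 14-day cutoff.
    """
    d = np.abs(np.asarray(distance_days, dtype=float))
    sigma = fwhm_days / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = np.exp(-d ** 2 / (2.0 * sigma ** 2))
    w = np.where(d > cutoff_days, 0.0, w)
    return w if w.ndim else float(w)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest value with cumulative weight >= 0.5."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / np.sum(w)
    return float(v[np.searchsorted(cum, 0.5 - 1e-12)])


def weighted_median_density(densities: np.ndarray,
                            weights: np.ndarray) -> np.ndarray | None:
    """Per-bin weighted median of recording densities, renormalised.

    Returns ``None`` when all weights are zero (empty grid point).  With
    equal weights this reduces to the ordinary per-bin (lower) median.
    """
    densities = np.atleast_2d(np.asarray(densities, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if np.all(weights == 0):
        return None
    keep = weights > 0
    d, w = densities[keep], weights[keep]
    order = np.argsort(d, axis=0, kind="stable")
    v_sorted = np.take_along_axis(d, order, axis=0)
    w_sorted = np.take_along_axis(np.broadcast_to(w[:, None], d.shape).copy(),
                                  order, axis=0)
    cum = np.cumsum(w_sorted, axis=0) / np.sum(w)
    idx = np.argmax(cum >= 0.5 - 1e-12, axis=0)
    med = v_sorted[idx, np.arange(d.shape[1])]
    area = float(np.sum(med) * BIN_WIDTH_S)
    if area <= 0:
        return None
    return med / area


def grid_for_axis(axis: str) -> np.ndarray:
    lo, hi = PMA_RANGE_WEEKS if axis == "pma" else GAP_RANGE_WEEKS
    n = int(round((hi - lo) / GRID_STEP_WEEKS))
    return lo + GRID_STEP_WEEKS * np.arange(n + 1)


def build_density_grid(axis_values_weeks, recording_densities,
                       axis: str = "pma",
                       grid_weeks: np.ndarray | None = None) -> DensityGrid:
    """Conditional IBI densities along PMA (31-36 wk) or gap (-3..3 wk).

    ``axis_values_weeks`` gives each recording's position on the
    conditioning axis; the grid runs at 1-day steps.  Grid points with
    no recording within the 14-day cutoff are marked empty.
    """
    if axis not in ("pma", "gap"):
        raise ValueError("axis must be 'pma' or 'gap'")
    vals = np.asarray(axis_values_weeks, dtype=float)
    dens = np.array([rd.density for rd in recording_densities])
    if len(vals) != len(dens) or len(vals) == 0:
        raise ValueError("need one axis value per recording density")
    grid = grid_for_axis(axis) if grid_weeks is None else np.asarray(grid_weeks)
    edges = recording_densities[0].bin_edges
    out = np.full((len(grid), dens.shape[1]), np.nan)
    cum = np.full_like(out, np.nan)
    empty = np.zeros(len(grid), dtype=bool)
    for i, g in enumerate(grid):
        w = gaussian_weights((vals - g) * 7.0)
        med = weighted_median_density(dens, w)
        if med is None:
            empty[i] = True
            continue
        out[i] = med
        cum[i] = np.cumsum(med) * BIN_WIDTH_S
    if empty.all():
        raise ValueError("no recording lies within 14 days of any grid point")
    return DensityGrid(axis=axis, axis_values=grid, bin_edges=edges,
                       densities=out, cumulative=cum, empty=empty)


def tail_mass(grid: DensityGrid, threshold_s: float = 15.0) -> np.ndarray:
    """P(IBI > threshold) per grid point -- the apnoea tail of the density."""
    left = grid.bin_edges[:-1]
    mask = left >= threshold_s
    return np.nansum(grid.densities[:, mask], axis=1) * BIN_WIDTH_S
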