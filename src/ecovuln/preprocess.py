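"""Preprocessing: compositing, gap filling, resampling, windowing, anomalies.

Turns raw input cubes into aligned, gap-filled, window-segmented,
standardized anomaly stacks ready for the per-pixel AR(1) fit:

* sub-monthly → monthly maximum-value composite (MVC), suppressing
  cloud-contaminated lows;
* single-pass 3×3 neighbourhood-mean gap filling within each time step;
* bilinear resampling between regular grids, with nodata excluded from
  the interpolation support;
* 5-year / 1-year-step moving windows anchored at their midpoint year;
* per-calendar-month z-score standardization inside each window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Grid, MonthlyCube

__all__ = [
    "MovingWindow",
    "monthly_composite_mvc",
    "fill_gaps_3x3",
    "resample_bilinear",
    "make_windows",
    "standardize_window",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# maximum value composite
# ---------------------------------------------------------------------------

def monthly_composite_mvc(cube: MonthlyCube) -> MonthlyCube:
    """Aggregate a sub-monthly cube to monthly by per-month maximum.

    Each month's value is the maximum over that month's non-missing
    observations; a month whose observations are all missing stays
    missing. Monthly input is returned unchanged with a warning.
    """
    if cube.cadence == "monthly":
        warnings.warn("input is already monthly; MVC is a no-op", stacklevel=2)
        return cube
    labels = cube.month_labels()
    months = pd.period_range(labels[0], labels[-1], freq="M")
    out = np.full((len(months), *cube.grid.shape), np.nan)
    codes = months.get_indexer(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for i in range(len(months)):
            sel = cube.values[codes == i]
            if len(sel):
                out[i] = np.nanmax(sel, axis=0)
    return MonthlyCube(out, months, cube.grid, cadence="monthly",
                       units=cube.units, attrs=dict(cube.attrs))


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

def fill_gaps_3x3(cube: MonthlyCube) -> MonthlyCube:
    """Fill missing pixels with the mean of valid 3×3 neighbours.

    Operates independently at each time step (same-date neighbourhood
    only). A missing pixel with at least one valid neighbour in its 3×3
    neighbourhood receives the mean of the valid neighbours; with zero
    valid neighbours it remains missing. Valid values are never altered.
    """
    from scipy.ndimage import convolve

    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0  # centre is the missing pixel itself
    out = cube.values.copy()
    n_filled = 0
    for t in range(cube.n_times):
        frame = out[t]
        valid = np.isfinite(frame)
        if valid.all():
            continue
        padded = np.where(valid, frame, 0.0)
        nbr_sum = convolve(padded, kernel, mode="constant", cval=0.0)
        nbr_cnt = convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
        fill = ~valid & (nbr_cnt > 0)
        frame[fill] = nbr_sum[fill] / nbr_cnt[fill]
        n_filled += int(fill.sum())
    log.info("gap filling: %d pixel-months filled", n_filled)
    out_cube = cube.copy_with(out)
    out_cube.attrs["n_gap_filled"] = n_filled
    return out_cube


# ---------------------------------------------------------------------------
# bilinear resampling
# ---------------------------------------------------------------------------

def resample_bilinear(cube: MonthlyCube, target_grid: Grid) -> MonthlyCube:
    """Bilinear resampling of a cube onto another regular grid.

    Nodata cells are excluded from the interpolation support: each target
    value is the bilinear-weight-renormalized mean over the valid subset
    of the four surrounding source cell centres. Targets outside the
    source cell-centre extent, or with no valid support, are missing.
    """
    src = cube.grid
    lat_t = target_grid.lats
    lon_t = target_grid.lons
    if (lat_t.max() < src.lats.min() or lat_t.min() > src.lats.max()
            or lon_t.max() < src.lons.min() or lon_t.min() > src.lons.max()):
        raise ValueError("target grid extent is disjoint from source grid")

    # fractional source indices of target cell centres
    fi = (src.origin_lat - lat_t) / src.cell_size          # rows (lat descending)
    fj = (lon_t - src.origin_lon) / src.cell_size          # cols
    fi2, fj2 = np.meshgrid(fi, fj, indexing="ij")
    inside = ((fi2 >= 0) & (fi2 <= src.n_rows - 1)
              & (fj2 >= 0) & (fj2 <= src.n_cols - 1))
    i0 = np.clip(np.floor(fi2).astype(int), 0, src.n_rows - 2) if src.n_rows > 1 \
        else np.zeros_like(fi2, dtype=int)
    j0 = np.clip(np.floor(fj2).astype(int), 0, src.n_cols - 2) if src.n_cols > 1 \
        else np.zeros_like(fj2, dtype=int)
    di = fi2 - i0
    dj = fj2 - j0
    w = np.stack([(1 - di) * (1 - dj), (1 - di) * dj, di * (1 - dj), di * dj])

    out = np.full((cube.n_times, *target_grid.shape), np.nan)
    for t in range(cube.n_times):
        frame = cube.values[t]
        corners = np.stack([frame[i0, j0], frame[i0, j0 + (src.n_cols > 1)],
                            frame[i0 + (src.n_rows > 1), j0],
                            frame[i0 + (src.n_rows > 1), j0 + (src.n_cols > 1)]])
        valid = np.isfinite(corners)
        wv = np.where(valid, w, 0.0)
        wsum = wv.sum(axis=0)
        num = np.where(valid, wv * corners, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = num / wsum
        vals[(wsum <= 0) | ~inside] = np.nan
        out[t] = vals
    return MonthlyCube(out, cube.time, target_grid, cadence=cube.cadence,
                       units=cube.units, attrs=dict(cube.attrs))


# ---------------------------------------------------------------------------
# moving windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovingWindow:
    """One fixed-length segment of the monthly series.

    ``month_slice`` indexes into a cube whose time axis starts at January
    of the series' first year; it covers exactly ``12 * length`` months.
    The midpoint year anchors the window's estimates in time.
    """

    start_year: int
    end_year: int
    midpoint_year: int
    month_slice: slice

    @property
    def length_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def n_months(self) -> int:
        return self.month_slice.stop - self.month_slice.start


def make_windows(start_year: int, end_year: int,
                 length_years: int = 5, step_years: int = 1) -> list[MovingWindow]:
    """Enumerate moving windows over [start_year, end_year].

    With the default 5-year length and 1-year step on 1983–2022 this
    yields 36 overlapping 60-month windows with midpoints 1985…2020.
    """
    span = end_year - start_year + 1
    if step_years < 1:
        raise ValueError("step_years must be >= 1")
    if span < length_years:
        raise ValueError(
            f"series span {span} yr is shorter than window length {length_years} yr")
    windows = []
    for w_start in range(start_year, end_year - length_years + 2, step_years):
        w_end = w_start + length_years - 1
        first_month = (w_start - start_year) * 12
        windows.append(MovingWindow(
            start_year=w_start,
            end_year=w_end,
            midpoint_year=w_start + length_years // 2,
            month_slice=slice(first_month, first_month + 12 * length_years),
        ))
    return windows


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_window(cube: MonthlyCube, window: MovingWindow, *,
                       mode: str = "per_month",
                       min_valid_fraction: float = 0.8) -> np.ndarray:
    """Z-score anomalies of one window slice of a monthly cube.

    mode="per_month" (default) standardizes each calendar-month group
    within the window separately (5 values per group for a 5-year
    window), which removes the seasonal cycle and yields the standard
    anomaly construction. mode="pooled" standardizes all window months
    together (sensitivity analysis). mode="none" passes values through
    unchanged, for inputs that are already anomalies.

    Standard deviations use the n−1 denominator. Pixels with less than
    ``min_valid_fraction`` of the window's months valid, or with a zero
    standard deviation in any month group (degenerate, e.g. a constant
    series), are fully masked in the output.

    Returns a ``(n_months, rows, cols)`` anomaly array with NaN where
    masked or missing.
    """
    if cube.cadence != "monthly":
        raise ValueError("standardize_window requires a monthly cube")
    if window.month_slice.stop > cube.n_times:
        raise ValueError("window slice extends beyond the cube's time axis")
    block = cube.values[window.month_slice].copy()
    n_months = block.shape[0]

    valid_frac = np.isfinite(block).sum(axis=0) / n_months
    low_cover = valid_frac < min_valid_fraction

    if mode == "none":
        out = block
        out[:, low_cover] = np.nan
        return out

    out = np.full_like(block, np.nan)
    degenerate = np.zeros(block.shape[1:], dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if mode == "per_month":
            for m in range(12):
                grp = block[m::12]
                mean = np.nanmean(grp, axis=0)
                sd = np.nanstd(grp, axis=0, ddof=1)
                degenerate |= np.isfinite(sd) & (sd == 0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    out[m::12] = (grp - mean) / sd
        elif mode == "pooled":
            mean = np.nanmean(block, axis=0)
            sd = np.nanstd(block, axis=0, ddof=1)
            degenerate |= np.isfinite(sd) & (sd == 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                out = (block - mean) / sd
        else:
            raise ValueError(f"unknown standardization mode {mode!r}")
    out[:, degenerate | low_cover] = np.nan
    out[~np.isfinite(out)] = np.nan
    return out
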