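"""Temporal dynamics: phases, per-pixel trends, conversions, centroids.

Four analyses of the midpoint-year index series:

* regional mean series per index, with coefficients of variation;
* inflection-point (breakpoint) detection on the regional series by
  continuous piecewise-linear regression — exhaustive search over
  candidate break years (the series has ≤ ~40 points), with the break
  count chosen by BIC;
* per-pixel OLS trends within each phase, classified Increasing /
  Decreasing / No-trend by a two-sided t-test at α = 0.05 (no
  multiple-testing correction by default, an FDR option exists);
* the phase-to-phase conversion typology (e.g. "D-I-D-I") and the
  centroid-shift track of each trend direction's spatial distribution.

Phase boundary years are included in both adjacent phases, matching the
convention of labelling phases "1985–1994, 1994–2008, …".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Grid
from .model import IndexSeries

__all__ = [
    "RegionalSeries",
    "PhaseSegmentation",
    "PhaseTrendMap",
    "ConversionMap",
    "CentroidTrack",
    "regional_series",
    "detect_phases",
    "phase_trend_map",
    "conversion_types",
    "centroid_track",
]

log = logging.getLogger(__name__)

_INDEX_KEYS = ("EI", "SI", "RI", "VI")


# ---------------------------------------------------------------------------
# regional series
# ---------------------------------------------------------------------------

@dataclass
class RegionalSeries:
    """Yearly zonal (regional) mean of each index, with CV (%)."""

    years: np.ndarray
    means: dict[str, np.ndarray]
    cv: dict[str, float]

    def mean_series(self, index: str) -> np.ndarray:
        return self.means[index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years,
                             **{k: self.means[k] for k in self.means}})


def regional_series(series: IndexSeries,
                    mask: np.ndarray | None = None) -> RegionalSeries:
    """Unweighted mean over valid masked pixels for each midpoint year.

    The coefficient of variation is 100·sd/mean over the yearly series
    (sd with the n−1 denominator).
    """
    if mask is not None and not mask.any():
        raise ValueError("empty mask")
    means: dict[str, np.ndarray] = {}
    cv: dict[str, float] = {}
    for k in _INDEX_KEYS:
        stack = series[k]
        if mask is not None:
            stack = np.where(mask[None], stack, np.nan)
        with np.errstate(invalid="ignore"):
            m = np.nanmean(stack.reshape(stack.shape[0], -1), axis=1)
        means[k] = m
        mu = np.nanmean(m)
        cv[k] = float(100.0 * np.nanstd(m, ddof=1) / mu) if mu != 0 else np.nan
    return RegionalSeries(series.years.copy(), means, cv)


# ---------------------------------------------------------------------------
# piecewise-linear phase detection
# ---------------------------------------------------------------------------

@dataclass
class PhaseSegmentation:
    """Continuous piecewise-linear segmentation of a regional series."""

    breakpoints: list[int]
    phases: list[dict]          # start, end, slope, p per phase
    n_breaks: int
    bic_by_k: dict[int, float]
    sse: float
    fitted: np.ndarray

    def phase_bounds(self) -> list[tuple[int, int]]:
        return [(p["start"], p["end"]) for p in self.phases]


def _hinge_design(t: np.ndarray, breaks: tuple[int, ...]) -> np.ndarray:
    cols = [np.ones_like(t, dtype=float), t.astype(float)]
    for b in breaks:
        cols.append(np.maximum(t - b, 0.0))
    return np.column_stack(cols)


_CANDIDATE_CACHE: dict[tuple, tuple[list, np.ndarray]] = {}


def _candidates(years: tuple[float, ...], m: int,
                min_segment: int) -> tuple[list, np.ndarray]:
    """Admissible m-break placements and their stacked thin-QR Q factors.

    Returns (combos, Q) where Q has shape (n_candidates, n, 2 + m); the
    SSE of every candidate is then one projection, so repeated searches
    over the same year grid (simulations, per-index fits) cost almost
    nothing beyond the first call.
    """
    key = (years, m, min_segment)
    if key in _CANDIDATE_CACHE:
        return _CANDIDATE_CACHE[key]
    t = np.asarray(years, dtype=float)
    y0, y1 = years[0], years[-1]
    interior = [y for y in years
                if y0 < y < y1 and y0 + min_segment <= y <= y1 - min_segment]
    combos = []
    for combo in itertools.combinations(interior, m):
        spans = np.diff([y0, *combo, y1])
        if m and (spans < min_segment).any():
            continue
        combos.append(combo)
    if combos:
        Q = np.stack([np.linalg.qr(_hinge_design(t, c))[0] for c in combos])
    else:
        Q = np.empty((0, len(t), 2 + m))
    _CANDIDATE_CACHE[key] = (combos, Q)
    return combos, Q


def detect_phases(years: np.ndarray, values: np.ndarray, *,
                  max_breaks: int = 4, min_segment: int = 3,
                  n_breaks: int | None = None) -> PhaseSegmentation:
    """Segment a regional series into linear phases joined at inflection years.

    For every admissible placement of 0..``max_breaks`` breakpoints at
    observed years (each phase spanning at least ``min_segment`` years),
    the continuous piecewise-linear model is fit by least squares and
    the SSE-minimizing placement per break count is kept; the break
    count is then selected by BIC, counting both the slope changes and
    the break locations as parameters (k = 2 + 2·breaks). Pass
    ``n_breaks`` to fix the break count instead.

    Per-phase slopes come from the joined fit; per-phase p-values are
    two-sided t-tests of the within-phase OLS slope (boundary years
    included in both adjacent phases).
    """
    if hasattr(years, "years"):  # accept a RegionalSeries for convenience
        raise TypeError("pass (years, values) arrays; see regional_series()")
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    n = len(values)
    counts = range(max_breaks + 1) if n_breaks is None else [n_breaks]
    needed = (max(counts) + 1) * min_segment
    if n < max(needed, 4):
        raise ValueError(f"series of {n} points is too short for "
                         f"{max(counts)} breaks with {min_segment}-yr phases")
    yty = float(values @ values)
    best_by_k: dict[int, tuple[float, tuple[int, ...]]] = {}
    for m in counts:
        combos, Q = _candidates(tuple(float(y) for y in years), m,
                                min_segment)
        if not combos:
            continue
        proj = np.einsum("cnk,n->ck", Q, values)
        sse_all = np.maximum(yty - (proj ** 2).sum(axis=1), 0.0)
        i_best = int(np.argmin(sse_all))
        best_by_k[m] = (float(sse_all[i_best]), combos[i_best])
    # Penalty counts intercept + base slope plus, per break, the slope
    # change, the break location, and one extra unit for the exhaustive
    # location search (changepoint-adjusted BIC; the plain 2 + 2m count
    # over-selects breaks under exhaustive search).
    bic_by_k = {m: n * np.log(max(sse, 1e-300) / n) + (2 + 3 * m) * np.log(n)
                for m, (sse, _) in best_by_k.items()}
    k_sel = min(bic_by_k, key=bic_by_k.get)
    sse, breaks = best_by_k[k_sel]

    X = _hinge_design(years.astype(float), breaks)
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    fitted = X @ coef
    slopes = np.cumsum(coef[1:])  # slope of phase j = base + hinge increments

    def _num(v):
        return int(v) if float(v).is_integer() else float(v)

    bounds = list(zip((years[0], *breaks), (*breaks, years[-1])))
    phases = []
    for (p0, p1), slope in zip(bounds, slopes):
        sel = (years >= p0) & (years <= p1)
        if sel.sum() >= 3:
            res = stats.linregress(years[sel], values[sel])
            p_val = float(res.pvalue)
        else:
            p_val = np.nan
        phases.append({"start": _num(p0), "end": _num(p1),
                       "slope": float(slope), "p": p_val})
    return PhaseSegmentation([_num(b) for b in breaks], phases, len(breaks),
                             bic_by_k, float(sse), fitted)


# ---------------------------------------------------------------------------
# per-pixel phase trends
# ---------------------------------------------------------------------------

@dataclass
class PhaseTrendMap:
    """Per-pixel trend of one index over one phase."""

    slope: np.ndarray
    p_value: np.ndarray
    trend_class: np.ndarray  # '<U1': 'I', 'D' or 'N'
    phase: tuple[int, int]
    grid: Grid
    index: str = "VI"


def phase_trend_map(series: IndexSeries, phase: tuple[int, int], *,
                    index: str = "VI", alpha: float = 0.05,
                    fdr: bool = False) -> PhaseTrendMap:
    """Per-pixel OLS trend of an index over a phase, classified I/D/N.

    The phase is inclusive of both boundary years. Class I: positive
    slope significant at ``alpha`` (two-sided t-test); D: negative and
    significant; N otherwise, including pixels with fewer than 3 valid
    time points (their slope is NaN). ``fdr=True`` applies a
    Benjamini–Hochberg correction before classifying (off by default).
    """
    start, end = phase
    sel = (series.years >= start) & (series.years <= end)
    if sel.sum() < 3:
        raise ValueError("phase must contain at least 3 midpoint years")
    x = series.years[sel].astype(float)
    Y = series[index][sel]
    valid = np.isfinite(Y)
    n = valid.sum(axis=0)

    import warnings as _warnings
    xm = np.where(valid, x[:, None, None], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        x_mean = np.nanmean(xm, axis=0)
        y_mean = np.nanmean(np.where(valid, Y, np.nan), axis=0)
        dx = np.where(valid, x[:, None, None] - x_mean[None], 0.0)
        dy = np.where(valid, Y - y_mean[None], 0.0)
        sxx = (dx * dx).sum(axis=0)
        sxy = (dx * dy).sum(axis=0)
        slope = sxy / sxx
        resid = dy - slope[None] * dx
        dof = n - 2
        s2 = np.where(valid, resid, 0.0)
        rss = (s2 * s2).sum(axis=0)
        se = np.sqrt(rss / np.maximum(dof, 1) / sxx)
        tstat = slope / se

    usable = (n >= 3) & np.isfinite(tstat)
    p = np.full(slope.shape, np.nan)
    p[usable] = 2.0 * stats.t.sf(np.abs(tstat[usable]), dof[usable])
    # a perfectly noiseless trend gives se == 0 -> t = inf -> p = 0
    exact = usable & np.isinf(tstat)
    p[exact] = 0.0

    p_cls = p.copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests
        flat_ok = np.isfinite(p)
        adj = np.full(p.shape, np.nan)
        if flat_ok.any():
            adj[flat_ok] = multipletests(p[flat_ok], method="fdr_bh")[1]
        p_cls = adj

    cls = np.full(slope.shape, "N", dtype="<U1")
    sig = usable & np.isfinite(p_cls) & (p_cls < alpha)
    cls[sig & (slope > 0)] = "I"
    cls[sig & (slope < 0)] = "D"
    slope = np.where(usable, slope, np.nan)
    return PhaseTrendMap(slope, p, cls, (start, end), series.grid, index)


# ---------------------------------------------------------------------------
# conversion typology
# ---------------------------------------------------------------------------

@dataclass
class ConversionMap:
    """Per-pixel concatenated trend codes across phases, with area shares."""

    codes: np.ndarray            # object array, e.g. "D-I-D-I"
    proportions: pd.DataFrame    # columns: code, percent (desc by area)
    grid: Grid

    @property
    def no_trend_code(self) -> str:
        n_phases = self.codes.flat[0].count("-") + 1
        return "-".join(["N"] * n_phases)


def conversion_types(maps: list[PhaseTrendMap],
                     mask: np.ndarray | None = None) -> ConversionMap:
    """Synthesize phase trend maps into per-pixel conversion codes.

    The canonical analysis uses 4 phases; any other count generalizes
    with a warning (the code length follows the phase count). Area
    percentages are computed over the analysis mask and always sum
    to 100.
    """
    if len(maps) != 4:
        log.warning("conversion typology defined for 4 phases; got %d",
                    len(maps))
    shp = maps[0].trend_class.shape
    for m in maps:
        if m.trend_class.shape != shp:
            raise ValueError("phase trend maps are not co-registered")
    letters = np.stack([m.trend_class for m in maps])
    codes = np.apply_along_axis("-".join, 0, letters.astype(object))
    if mask is None:
        mask = np.ones(shp, dtype=bool)
    flat = codes[mask]
    counts = pd.Series(flat).value_counts()
    table = (100.0 * counts / counts.sum()).rename("percent").reset_index()
    table.columns = ["code", "percent"]
    return ConversionMap(codes, table, maps[0].grid)


# ---------------------------------------------------------------------------
# centroid tracking
# ---------------------------------------------------------------------------

_KM_PER_DEG_LAT = 110.574
_KM_PER_DEG_LON_EQ = 111.320


@dataclass
class CentroidTrack:
    """Weighted centroids of one trend direction across phases."""

    direction: str
    weighting: str
    centroids: list[tuple[float, float] | None]  # (lat, lon) per phase
    displacements: list[dict]  # bearing_deg (cw from north), distance_km
    phases: list[tuple[int, int]] = field(default_factory=list)


def centroid_track(maps: list[PhaseTrendMap], direction: str = "I", *,
                   weighting: str = "binary") -> CentroidTrack:
    """Track the weighted centroid of a trend direction across phases.

    Per phase, the centroid is the weighted mean of the qualifying
    cells' centre coordinates — weights are 1 ("binary", default) or
    the absolute trend slope ("abs_slope"). A phase with no qualifying
    cell gets a None centroid and is flagged by a NaN displacement.

    Distances and bearings use a local equirectangular metric: one
    degree of longitude is scaled by cos(latitude), so east–west spans
    are not inflated at high latitude. Bearing is measured clockwise
    from north in degrees.
    """
    if direction not in ("I", "D"):
        raise ValueError("direction must be 'I' or 'D'")
    if weighting not in ("binary", "abs_slope"):
        raise ValueError("weighting must be 'binary' or 'abs_slope'")
    centroids: list[tuple[float, float] | None] = []
    for m in maps:
        qual = m.trend_class == direction
        if weighting == "abs_slope":
            qual &= np.isfinite(m.slope)
        if not qual.any():
            log.warning("phase %s: no qualifying '%s' cells; centroid "
                        "undefined", m.phase, direction)
            centroids.append(None)
            continue
        lat2d, lon2d = m.grid.cell_centers()
        w = np.abs(m.slope[qual]) if weighting == "abs_slope" \
            else np.ones(qual.sum())
        wsum = w.sum()
        centroids.append((float((w * lat2d[qual]).sum() / wsum),
                          float((w * lon2d[qual]).sum() / wsum)))
    displacements = []
    for c0, c1 in zip(centroids[:-1], centroids[1:]):
        if c0 is None or c1 is None:
            displacements.append({"bearing_deg": np.nan, "distance_km": np.nan})
            continue
        lat_mid = 0.5 * (c0[0] + c1[0])
        dy = (c1[0] - c0[0]) * _KM_PER_DEG_LAT
        dx = (c1[1] - c0[1]) * _KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(lat_mid))
        displacements.append({
            "bearing_deg": float(np.degrees(np.arctan2(dx, dy)) % 360.0),
            "distance_km": float(np.hypot(dx, dy)),
        })
    return CentroidTrack(direction, weighting, centroids, displacements,
                         [m.phase for m in maps])
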