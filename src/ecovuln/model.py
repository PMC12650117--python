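"""Windowed AR(1) climate-response model and the vulnerability indices.

Within every 5-year moving window and at every pixel, monthly
standardized anomalies are related by a lag-1 autoregression

    z_t = α·T'_t + β·P'_t + γ·z_{t−1} + ε_t

fit by ordinary least squares without intercept (anomalies are mean-zero
by construction; an intercept mode exists for the pooled-standardization
variant). The coefficients measure instantaneous temperature response
(α), precipitation response (β) and ecosystem memory (γ), and are
composed into four indices per window, after min-max scaling across the
spatial domain:

    RI = 1 − γ′                    (resilience: less memory, faster recovery)
    EI ∝ α′ + β′                   (exposure: total climate response)
    SI ∝ α′·T_norm + β′·P_norm     (sensitivity: response weighted by the
                                    window's normalized mean climate state)
    VI = EI·SI / (1 + RI)          (vulnerability)

|α| and |β| are scaled by magnitude (a strong response of either sign
means low resistance); γ is scaled signed. EI and SI raw sums (range up
to 2) are re-scaled to [0, 1] per window so VI lies in [0, 1]; the raw
sums are also kept. All min-max constants are recorded per window so
runs remain comparable post hoc.

The public surface is the statsmodels-style pair
:class:`VulnerabilityModel` / :class:`VulnerabilityResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid, MonthlyCube
from .preprocess import MovingWindow, make_windows, standardize_window

__all__ = [
    "ARFitField",
    "IndexSeries",
    "fit_ar1",
    "normalize_coefficients",
    "climate_window_norms",
    "compose_indices",
    "run_assessment",
    "VulnerabilityModel",
    "VulnerabilityResults",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-window AR(1) fit
# ---------------------------------------------------------------------------

@dataclass
class ARFitField:
    """Per-pixel AR(1) regression results for one window."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    resid_var: np.ndarray
    n_obs: np.ndarray
    fit_ok: np.ndarray
    window: MovingWindow | None = None


def fit_ar1(ndvi_anom: np.ndarray, temp_anom: np.ndarray,
            precip_anom: np.ndarray, *, min_obs: int = 10,
            intercept: bool = False,
            window: MovingWindow | None = None) -> ARFitField:
    """Per-pixel OLS of z_t on (T'_t, P'_t, z_{t−1}) for one window.

    The window's first month serves only as the lag, so a 60-month
    window yields at most 59 usable (t, t−1) pairs. Months where any
    regressor or the response is missing are dropped pairwise. Pixels
    with fewer than ``min_obs`` usable pairs, or a rank-deficient design
    (e.g. perfectly collinear regressors), get ``fit_ok = False`` and
    NaN coefficients.

    Solved by normal equations vectorized over pixels; equivalent to an
    independent per-pixel least-squares solve to high precision.
    """
    if not (ndvi_anom.shape == temp_anom.shape == precip_anom.shape):
        raise ValueError("anomaly stacks must share one shape")
    y = ndvi_anom[1:]
    regs = [temp_anom[1:], precip_anom[1:], ndvi_anom[:-1]]
    if intercept:
        regs.append(np.ones_like(y))
    X = np.stack(regs)  # (p, n, r, c)
    p = X.shape[0]

    valid = np.isfinite(y)
    for k in range(p):
        valid &= np.isfinite(X[k])
    Xv = np.where(valid[None], X, 0.0)
    yv = np.where(valid, y, 0.0)

    # normal equations per pixel: (p, p, r, c) and (p, r, c)
    XtX = np.einsum("inrc,jnrc->ijrc", Xv, Xv)
    Xty = np.einsum("inrc,nrc->irc", Xv, yv)
    yty = np.einsum("nrc,nrc->rc", yv, yv)
    n_obs = valid.sum(axis=0)

    shp = y.shape[1:]
    A = XtX.reshape(p, p, -1).transpose(2, 0, 1)
    b = Xty.reshape(p, -1).T
    sv = np.linalg.svd(A, compute_uv=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        well_posed = (sv[:, -1] > 1e-10 * np.maximum(sv[:, 0], 1e-300))
    ok = well_posed.reshape(shp) & (n_obs >= max(min_obs, p + 1))

    coef = np.full((A.shape[0], p), np.nan)
    idx = np.flatnonzero(ok.ravel())
    if idx.size:
        coef[idx] = np.linalg.solve(A[idx], b[idx][..., None])[..., 0]
    coef = coef.T.reshape(p, *shp)

    rss = yty - np.einsum("irc,irc->rc", np.nan_to_num(coef), Xty)
    rss = np.maximum(rss, 0.0)
    dof = n_obs - p
    with np.errstate(invalid="ignore", divide="ignore"):
        resid_var = np.where(ok & (dof > 0), rss / np.maximum(dof, 1), np.nan)
    coef[:, ~ok] = np.nan

    return ARFitField(alpha=coef[0], beta=coef[1], gamma=coef[2],
                      resid_var=resid_var, n_obs=n_obs, fit_ok=ok,
                      window=window)


# ---------------------------------------------------------------------------
# min-max scaling
# ---------------------------------------------------------------------------

def _minmax(surface: np.ndarray, valid: np.ndarray,
            label: str) -> tuple[np.ndarray, float, float]:
    """Min-max scale ``surface`` over ``valid`` pixels to [0, 1].

    A constant field maps every valid pixel to 0.5 (degenerate scaling,
    with a warning). Invalid pixels become NaN.
    """
    vals = surface[valid & np.isfinite(surface)]
    if vals.size < 1:
        raise ValueError(f"no valid pixels to scale for {label}")
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full(surface.shape, np.nan)
    use = valid & np.isfinite(surface)
    if hi == lo:
        warnings.warn(f"{label}: constant field, min-max scaling is degenerate; "
                      "all pixels set to 0.5", stacklevel=3)
        out[use] = 0.5
    else:
        out[use] = (surface[use] - lo) / (hi - lo)
    return out, lo, hi


def normalize_coefficients(fit: ARFitField, mask: np.ndarray | None = None
                           ) -> tuple[dict[str, np.ndarray], dict[str, tuple]]:
    """Min-max scale the fitted coefficients across the spatial domain.

    |α| and |β| are scaled (response magnitude is what matters for
    exposure); γ is scaled as-is. Scaling is per window over all valid
    pixels; the (min, max) pairs are returned for provenance.
    """
    valid = fit.fit_ok if mask is None else (fit.fit_ok & mask)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid pixels to normalize")
    alpha_n, a_lo, a_hi = _minmax(np.abs(fit.alpha), valid, "alpha")
    beta_n, b_lo, b_hi = _minmax(np.abs(fit.beta), valid, "beta")
    gamma_n, g_lo, g_hi = _minmax(fit.gamma, valid, "gamma")
    scaled = {"alpha": alpha_n, "beta": beta_n, "gamma": gamma_n}
    constants = {"alpha": (a_lo, a_hi), "beta": (b_lo, b_hi),
                 "gamma": (g_lo, g_hi)}
    return scaled, constants


def climate_window_norms(temp: MonthlyCube, precip: MonthlyCube,
                         window: MovingWindow,
                         mask: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray, dict[str, tuple]]:
    """Window-mean climate state, min-max scaled across the domain.

    Per pixel: mean of the raw temperature (resp. precipitation) over
    the window's months, then scaled to [0, 1] over valid pixels. These
    are the climate weights of the sensitivity index.
    """
    if window.month_slice.stop > temp.n_times:
        raise ValueError("window extends beyond the climate cubes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_mean = np.nanmean(temp.values[window.month_slice], axis=0)
        p_mean = np.nanmean(precip.values[window.month_slice], axis=0)
    valid = np.isfinite(t_mean) & np.isfinite(p_mean)
    if mask is not None:
        valid &= mask
    t_norm, t_lo, t_hi = _minmax(t_mean, valid, "temperature")
    p_norm, p_lo, p_hi = _minmax(p_mean, valid, "precipitation")
    return t_norm, p_norm, {"T": (t_lo, t_hi), "P": (p_lo, p_hi)}


def compose_indices(alpha_n: np.ndarray, beta_n: np.ndarray,
                    gamma_n: np.ndarray, t_norm: np.ndarray,
                    p_norm: np.ndarray
                    ) -> tuple[dict[str, np.ndarray], dict[str, tuple]]:
    """Compose EI, SI, RI and VI from normalized inputs for one window.

    RI = 1 − γ′ exactly. EI_raw = α′ + β′ and
    SI_raw = α′·T_norm + β′·P_norm (ranges up to 2) are min-max
    re-scaled to [0, 1] across the domain before entering
    VI = EI·SI/(1 + RI), so every stored index lies in [0, 1]. Raw sums
    are returned alongside for transparency.
    """
    for name, arr in (("alpha'", alpha_n), ("beta'", beta_n),
                      ("gamma'", gamma_n), ("T_norm", t_norm),
                      ("P_norm", p_norm)):
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError(f"{name} outside [0, 1]: upstream contract violated")

    valid = (np.isfinite(alpha_n) & np.isfinite(beta_n) & np.isfinite(gamma_n)
             & np.isfinite(t_norm) & np.isfinite(p_norm))
    ri = np.where(valid, 1.0 - gamma_n, np.nan)
    ei_raw = np.where(valid, alpha_n + beta_n, np.nan)
    si_raw = np.where(valid, alpha_n * t_norm + beta_n * p_norm, np.nan)
    ei, e_lo, e_hi = _minmax(ei_raw, valid, "EI")
    si, s_lo, s_hi = _minmax(si_raw, valid, "SI")
    vi = ei * si / (1.0 + ri)
    out = {"EI": ei, "SI": si, "RI": ri, "VI": vi,
           "EI_raw": ei_raw, "SI_raw": si_raw,
           "T_norm": t_norm, "P_norm": p_norm}
    return out, {"EI": (e_lo, e_hi), "SI": (s_lo, s_hi)}


# ---------------------------------------------------------------------------
# the index series container
# ---------------------------------------------------------------------------

_INDEX_VARS = ("EI", "SI", "RI", "VI", "EI_raw", "SI_raw", "T_norm", "P_norm")


@dataclass
class IndexSeries:
    """Per-pixel EI/SI/RI/VI stacks indexed by window midpoint year."""

    years: np.ndarray           # midpoint years, (n_windows,)
    data: dict[str, np.ndarray]  # each (n_windows, rows, cols)
    grid: Grid
    scaling_log: list[dict] = field(default_factory=list)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    @property
    def n_windows(self) -> int:
        return len(self.years)

    def subset_years(self, start: int, end: int) -> "IndexSeries":
        """Windows with midpoint year in [start, end] inclusive."""
        sel = (self.years >= start) & (self.years <= end)
        return IndexSeries(self.years[sel],
                           {k: v[sel] for k, v in self.data.items()},
                           self.grid, self.scaling_log)

    def to_dataset(self):
        """Convert to an :class:`xarray.Dataset` (midpoint_year, row, col)."""
        import xarray as xr
        coords = {"midpoint_year": self.years,
                  "lat": ("row", self.grid.lats),
                  "lon": ("col", self.grid.lons)}
        data_vars = {k: (("midpoint_year", "row", "col"), v)
                     for k, v in self.data.items()}
        ds = xr.Dataset(data_vars, coords=coords)
        ds.attrs["crs"] = self.grid.crs
        return ds


# ---------------------------------------------------------------------------
# assessment driver
# ---------------------------------------------------------------------------

def run_assessment(ndvi: MonthlyCube, temp: MonthlyCube, precip: MonthlyCube,
                   windows: list[MovingWindow],
                   mask: np.ndarray | None = None, *,
                   standardization: str = "per_month",
                   min_valid_fraction: float = 0.8,
                   min_obs: int = 10) -> tuple[IndexSeries, list[ARFitField]]:
    """Run the windowed assessment over preprocessed, co-registered cubes.

    For each window: standardize anomalies, fit the AR(1) model per
    pixel, min-max normalize, and compose the indices. Returns the
    midpoint-year :class:`IndexSeries` and the per-window raw fits.
    """
    ndvi.align_check(temp)
    ndvi.align_check(precip)
    intercept = standardization == "pooled"
    years = np.array([w.midpoint_year for w in windows])
    data = {k: np.full((len(windows), *ndvi.grid.shape), np.nan)
            for k in _INDEX_VARS}
    scaling_log: list[dict] = []
    fits: list[ARFitField] = []
    for i, w in enumerate(windows):
        z = standardize_window(ndvi, w, mode=standardization,
                               min_valid_fraction=min_valid_fraction)
        tz = standardize_window(temp, w, mode=standardization,
                                min_valid_fraction=min_valid_fraction)
        pz = standardize_window(precip, w, mode=standardization,
                                min_valid_fraction=min_valid_fraction)
        fit = fit_ar1(z, tz, pz, min_obs=min_obs, intercept=intercept,
                      window=w)
        fits.append(fit)
        scaled, coef_consts = normalize_coefficients(fit, mask)
        t_norm, p_norm, clim_consts = climate_window_norms(
            temp, precip, w, fit.fit_ok if mask is None else fit.fit_ok & mask)
        out, idx_consts = compose_indices(scaled["alpha"], scaled["beta"],
                                          scaled["gamma"], t_norm, p_norm)
        for k in _INDEX_VARS:
            data[k][i] = out[k]
        scaling_log.append({"midpoint_year": int(w.midpoint_year),
                            "coefficients": coef_consts,
                            "climate": clim_consts, "indices": idx_consts})
        log.debug("window %d/%d (midpoint %d): %d/%d pixels fit",
                  i + 1, len(windows), w.midpoint_year,
                  int(fit.fit_ok.sum()), fit.fit_ok.size)
    return IndexSeries(years, data, ndvi.grid, scaling_log), fits


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------

class VulnerabilityModel:
    """Moving-window AR(1) vulnerability model over three raster cubes.

    Parameters
    ----------
    ndvi, temp, precip : MonthlyCube
        Co-registered monthly cubes (NDVI dimensionless, temperature °C,
        precipitation mm) covering whole calendar years.
    window_length, window_step : int
        Moving-window length and step in years (defaults 5 and 1).
    standardization : {"per_month", "pooled", "none"}
        Anomaly convention inside each window. "per_month" (default)
        z-scores each calendar-month group; "pooled" z-scores the whole
        window and adds an intercept to the regression; "none" passes
        the inputs through (for data that are already anomalies).
    mask : bool array, optional
        Analysis mask (e.g. stable-ecosystem pixels); pixels outside it
        are excluded from normalization statistics and outputs.
    """

    def __init__(self, ndvi: MonthlyCube, temp: MonthlyCube,
                 precip: MonthlyCube, *, window_length: int = 5,
                 window_step: int = 1, standardization: str = "per_month",
                 min_valid_fraction: float = 0.8, min_obs: int = 10,
                 mask: np.ndarray | None = None):
        if ndvi.cadence != "monthly":
            raise ValueError("NDVI cube must be monthly; apply the maximum "
                             "value composite to sub-monthly data first")
        ndvi.align_check(temp)
        ndvi.align_check(precip)
        self.ndvi, self.temp, self.precip = ndvi, temp, precip
        self.window_length = window_length
        self.window_step = window_step
        self.standardization = standardization
        self.min_valid_fraction = min_valid_fraction
        self.min_obs = min_obs
        self.mask = mask
        t = ndvi.time
        self.start_year, self.end_year = int(t[0].year), int(t[-1].year)
        self.windows = make_windows(self.start_year, self.end_year,
                                    window_length, window_step)

    @classmethod
    def from_scene(cls, scene: dict, **kwargs) -> "VulnerabilityModel":
        """Build from a :func:`ecovuln.synthetic.simulate_scene` output."""
        return cls(scene["ndvi"], scene["temp"], scene["precip"], **kwargs)

    def fit(self) -> "VulnerabilityResults":
        indices, fits = run_assessment(
            self.ndvi, self.temp, self.precip, self.windows, self.mask,
            standardization=self.standardization,
            min_valid_fraction=self.min_valid_fraction, min_obs=self.min_obs)
        return VulnerabilityResults(self, indices, fits)


class VulnerabilityResults:
    """Fitted vulnerability assessment: index stacks plus diagnostics."""

    def __init__(self, model: VulnerabilityModel, indices: IndexSeries,
                 fits: list[ARFitField]):
        self.model = model
        self.indices = indices
        self.fits = fits

    @property
    def years(self) -> np.ndarray:
        return self.indices.years

    def coefficient_stack(self, name: str) -> np.ndarray:
        """Raw per-window coefficient surfaces, shape (n_windows, r, c)."""
        return np.stack([getattr(f, name) for f in self.fits])

    def multi_year_mean(self, index: str = "VI",
                        min_valid_fraction: float = 0.5) -> np.ndarray:
        from .spatial import multi_year_mean
        return multi_year_mean(self.indices, index,
                               min_valid_fraction=min_valid_fraction)

    def regional_series(self, mask: np.ndarray | None = None):
        from .temporal import regional_series
        return regional_series(self.indices,
                               mask if mask is not None else self.model.mask)

    def phase_trend_map(self, phase: tuple[int, int], index: str = "VI",
                        alpha: float = 0.05):
        from .temporal import phase_trend_map
        return phase_trend_map(self.indices, phase, index=index, alpha=alpha)

    def summary(self) -> str:
        """Plain-text overview of the fitted assessment."""
        reg = self.regional_series()
        ok_frac = np.mean([f.fit_ok.mean() for f in self.fits])
        lines = [
            "Ecosystem vulnerability assessment (moving-window AR(1))",
            "=" * 58,
            f"grid: {self.indices.grid.n_rows} x {self.indices.grid.n_cols}"
            f"  |  windows: {self.indices.n_windows}"
            f" ({self.model.window_length}-yr length,"
            f" {self.model.window_step}-yr step)",
            f"midpoint years: {self.years[0]}-{self.years[-1]}"
            f"  |  mean pixel fit rate: {100 * ok_frac:.1f}%",
            "",
            f"{'index':>6} {'mean':>8} {'min':>8} {'max':>8} {'CV %':>8}",
        ]
        for k in ("EI", "SI", "RI", "VI"):
            s = reg.mean_series(k)
            lines.append(f"{k:>6} {np.nanmean(s):8.3f} {np.nanmin(s):8.3f} "
                         f"{np.nanmax(s):8.3f} {reg.cv[k]:8.2f}")
        return "\n".join(lines)

    def plot_series(self, ax=None, indices=("EI", "SI", "RI", "VI")):
        """Plot the regional mean of each index against midpoint year."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        reg = self.regional_series()
        for k in indices:
            ax.plot(reg.years, reg.mean_series(k), marker="o", ms=3, label=k)
        ax.set_xlabel("window midpoint year")
        ax.set_ylabel("regional mean index")
        ax.legend(frameon=False)
        return ax
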