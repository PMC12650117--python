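# Methods

This note records the statistical model, the synthetic-data design, the
numerical choices, and the known limitations of `ecovuln`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The assessment model

### Windowed AR(1) climate response

The core object is a per-pixel lag-1 autoregression of monthly
standardized NDVI anomalies on contemporaneous standardized climate
anomalies and the previous month's NDVI anomaly,

    z_t = α·T′_t + β·P′_t + γ·z_{t−1} + ε_t ,   ε_t ~ N(0, σ²),

fit independently inside each moving window (default 5 years = 60
months, stepped 1 year, midpoint-year anchored). Assumptions: linearity
of the anomaly response, within-window stationarity (supported by the
anomaly construction), and Gaussian residuals. The fit is OLS without
intercept — per-calendar-month z-scoring makes every regressor and the
response mean-zero by construction, so an intercept would only absorb
sampling noise. A pooled-window standardization mode exists for
sensitivity analysis; it does not remove the seasonal means exactly, so
in that mode the regression carries an intercept.

The window's first month serves only as the lag, so a 60-month window
gives at most 59 usable (t, t−1) pairs. Months missing any variable are
dropped pairwise; pixels with fewer than `min_obs = 10` pairs, or a
rank-deficient design (e.g. collinear regressors), are flagged
`fit_ok = False` and excluded from all downstream statistics. The
solver is normal equations vectorized across pixels with an SVD
condition check (smallest/largest singular value > 1e-10); tests verify
agreement with per-pixel `lstsq` to 1e-8 and exact inversion of
noiseless data.

### Anomaly convention

"Standardized anomalies" are computed per calendar month *within each
window*: each month-group of 5 values is z-scored with the n−1
denominator. This removes the seasonal cycle — the standard anomaly
construction — at the cost of very short month-groups (5 values), which
is why the n−1 choice is material and fixed. Pixels retaining fewer
than 80% of the window's months after gap filling, or with a zero
standard deviation in any month group (constant series), are masked for
that window.

### Index composition

Per window, over all pixels with a valid fit (and inside the analysis
mask if one is set):

* |α| and |β| are min-max scaled to [0, 1] — the indices respond to the
  *magnitude* of the climate response; a strong negative response means
  low resistance just as a strong positive one does. γ is scaled
  signed.
* `RI = 1 − γ′` exactly.
* `EI_raw = α′ + β′` and `SI_raw = α′·T_norm + β′·P_norm` can reach 2;
  both are min-max re-scaled to [0, 1] per window before composing
  `VI = EI·SI/(1 + RI)`, so every stored index lies in [0, 1]. The raw
  sums are emitted alongside for transparency.
* `T_norm`, `P_norm` are min-max scaled window means of the raw climate.
* Scaling is per window, never across windows — cross-window scaling
  would leak information from late windows into early ones. Every
  min/max constant is logged per window so runs remain comparable post
  hoc.
* A constant field under min-max scaling maps all pixels to 0.5 with a
  warning (declared degenerate fallback).

The identity `VI·(1 + RI) = EI·SI` holds to 1e-12 pixelwise and is
asserted in the acceptance suite.

## 2. Downstream analyses

* **Stable-ecosystem mask** — pixels whose land-cover class is
  identical in every provided annual map and belongs to the five
  ecosystem classes. Adding years can only shrink the mask (tested).
* **Zonal profiles** — surfaces are averaged within fixed-width
  coordinate bins under an exact floor convention (bin k is
  [k·w, (k+1)·w)); gradients are fit by unweighted OLS on the bin means
  (a count-weighted option exists), or by the shared one-break
  segmented fit.
* **Ecosystem ANOVA** — one-way ANOVA plus Tukey–Kramer HSD
  (statsmodels `pairwise_tukeyhsd`, which applies the Kramer adjustment
  for unequal group sizes) at α = 0.05, with a compact letter display
  built by the insert-and-absorb algorithm (start from one all-class
  group, split on each significant pair, absorb contained groups).
* **Phase detection** — continuous piecewise-linear regression of the
  regional yearly series, breakpoints restricted to observed years with
  every phase spanning ≥ 3 years, all placements enumerated
  exhaustively (the series has ≤ ~40 points). The break count
  (0…`max_breaks`, default 4) is selected by a changepoint-adjusted BIC
  with k = 2 + 3m parameters: intercept, base slope, and per break the
  slope change, the location, and one extra unit reflecting the
  exhaustive location search. The plain 2 + 2m count over-selects
  breaks under exhaustive search; with the adjusted penalty a noisy
  four-phase series is recovered and a noisy linear series is left
  unsegmented at the rates the acceptance script measures. Per-phase
  p-values are two-sided t-tests on the within-phase OLS slope.
* **Phase trends and conversions** — per-pixel OLS slope of an index on
  midpoint year within a phase, classified I/D/N by a two-sided t-test
  at α = 0.05 with no multiple-testing correction (a Benjamini–Hochberg
  option exists, off by default). Phase boundary years belong to both
  adjacent phases, matching phase labels of the form "1985–1994,
  1994–2008, …". Conversion codes concatenate the per-phase classes;
  their area shares always partition the analysis mask.
* **Centroid tracking** — per phase, the centroid of one trend
  direction's qualifying cells, with binary weights by default (each
  significant cell counts once) or |slope| weights. Displacements use a
  local equirectangular metric — Δlat·110.574 km and
  Δlon·111.320·cos(lat) km — with bearing clockwise from north. At the
  regional extents modelled this approximation is well inside the ±20°
  bearing tolerance the tests use; no projection library is required.

## 3. The synthetic-data generator

The generator is first-class, tested code: it is the ground truth every
downstream stage is validated against.

What it emulates: seasonal climate cycles (sinusoidal, amplitudes 12 °C
and 60 mm/month by default) with latitudinal gradients; phase-wise
continuous piecewise-linear climate drift (default breaks 1994, 2008,
2011 with slopes −0.008, +0.005, −0.050, 0.0 standardized units/yr, one
unit = 1 °C of temperature and −10 mm of monthly precipitation); NDVI
generated by the same AR(1) process the model fits, from prescribed
per-pixel (α, β, γ) surfaces (smooth latitudinal ramps plus correlated
noise, coefficients within [0.05, 0.7]); biweekly sampling (days 1 and
16, the second observation randomly degraded so an MVC recovers the
clean value) with configurable dropout; and 5-class land cover with a
nodata class and an optional step change for stable-mask tests.

Key design decisions:

* **Initialization** — the anomaly recursion starts at its stationary
  mean 0 and discards a 12-month burn-in (recycling the first year's
  climate), so short windows see no transient.
* **Unit stationary variance** (`equalize_variance=True`, default) —
  the per-pixel innovation sd is set to
  σ² = (1 − γ²) − α² − β² (floored at 0.05), giving the anomaly
  process unit variance everywhere. This matters: the pipeline
  re-standardizes NDVI per window, which divides the fitted
  coefficients by the pixel's anomaly sd; with spatially varying
  variance that division would invert the prescribed exposure ranking.
  With unit variance the ranking of (α, β) and the exact value of γ
  survive standardization. Setting `noise_sd_ndvi=0` disables
  equalization and gives the exactly invertible noiseless process.
* **One unambiguous gradient** — the latitudinal climate pattern places
  the climatically stressed end in the north, so the window-mean
  climate weights (T_norm, P_norm) reinforce the northward coefficient
  gradient instead of fighting it; all four indices then share a single
  ground-truth north–south gradient.
* **Latitude-balanced land cover** — class proportions (default
  grassland 0.40, forest 0.25, shrubland 0.15, cropland 0.10, wetland
  0.10, chosen so every class is well sampled) are enforced within each
  grid row by rank-based quantiles of a smooth random field. Every
  class then has the same latitude distribution, so ecosystem
  comparisons are orthogonal to the latitudinal gradients by
  construction.
* **A deliberately fragile class** — wetland pixels get α + 0.15 and
  γ + 0.15, making them the most exposed and least resilient class;
  the ecosystem ANOVA must single them out.
* **De-standardization** — NDVI = 0.45 + seasonal cycle (amplitude
  0.15) + 0.08·z, clipped to [−0.2, 1] with the clipping fraction
  logged. Nodata is NaN internally and the file's declared fill value
  on disk.

What it does **not** emulate: satellite orbital-drift artifacts, sensor
fusion, real cloud statistics (dropouts are i.i.d.), spatially
correlated innovation noise, non-Gaussian residuals, and land-use
change processes beyond a single step change. Passing tests therefore
demonstrate correctness of the estimation machinery under the model's
own assumptions — not robustness to the full error structure of real
satellite records.

## 4. Problem sizes and reproducibility

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the statistical contracts are
sharp: 10–40 pixel grids for unit tests, 1,000 replicate pixels for
coefficient recovery, 10,000 null series for trend-test calibration,
100 replicates for breakpoint recovery, and one 100×100, 40-year scene
(36 windows) for the end-to-end gradient and ecosystem checks. Every
generator is bit-reproducible under a fixed seed; the pipeline writes a
manifest with SHA-256 hashes of all outputs, and identical seeds yield
identical hashes.

## 5. Known limitations

* The AR(1) coefficients are descriptive regression quantities;
  `RI = 1 − γ′` is a relative, domain-normalized resilience, not an
  absolute recovery rate. Min-max scaling makes all indices
  domain-relative: values are not comparable across study regions.
* Whether min-max scaling should be per window or pooled across windows
  is genuinely open; per-window is the default (no temporal leakage)
  and the constants are logged so either view can be reconstructed.
* EI and SI are re-scaled sums (the literal α′+β′ can reach 2); the raw
  sums are emitted so users who prefer the unscaled definition can use
  `EI_raw`/`SI_raw` directly.
* Per-pixel trend tests are uncorrected for multiplicity by design
  (α = 0.05 per pixel); the FDR option changes the I/D/N maps
  materially when used.
* Gap filling is a single-pass, same-time-step 3×3 neighbourhood mean;
  it cannot fill the interior of large gaps and is not a temporal
  interpolator.
* NetCDF (classic format) is the raster interchange format; GeoTIFF is
  not written.
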