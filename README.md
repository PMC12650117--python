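# ecovuln

Moving-window AR(1) assessment of terrestrial-ecosystem vulnerability to
climate variability, for gridded monthly vegetation-index and climate
time series.

## The problem

How vulnerable is vegetation to climate fluctuations, where, and how has
that vulnerability changed over decades? `ecovuln` answers this with a
per-pixel statistical decomposition of vulnerability into **exposure**
(how strongly vegetation responds to climate), **sensitivity** (how much
impact the prevailing climate state exerts through that response) and
**resilience** (how quickly vegetation returns to its mean state), all
estimated from the data themselves rather than from expert weighting.
It is aimed at researchers working with long satellite NDVI records
(e.g. GIMMS-class products) and gridded temperature/precipitation data,
and at method developers who need a fully synthetic, ground-truthed
testbed for this family of indices.

## The model

Within every 5-year moving window (60 months, stepped annually) and at
every pixel, monthly standardized anomalies obey a lag-1 autoregression

    z_t = α·T′_t + β·P′_t + γ·z_{t−1} + ε_t

where z is the NDVI anomaly, T′ and P′ the temperature and
precipitation anomalies (z-scored per calendar month within the
window), and ε Gaussian noise. The fit is ordinary least squares without
intercept. γ measures ecosystem memory; α and β measure the
instantaneous climate response. After min-max scaling of |α|, |β| and γ
across the spatial domain (per window), the indices are

    RI = 1 − γ′                     resilience
    EI ∝ α′ + β′                    exposure
    SI ∝ α′·T_norm + β′·P_norm      sensitivity
    VI = EI·SI / (1 + RI)           vulnerability

with T_norm, P_norm the min-max scaled window-mean climate state. Each
window's indices are anchored at its midpoint year, giving annual index
maps (1985–2020 for a 1983–2022 record). Downstream analyses cover
zonal gradients (binned latitude/longitude/elevation profiles with
linear or segmented fits), ecosystem comparisons (one-way ANOVA with
Tukey–Kramer letters over a stable-land-cover mask), regional phase
detection (exhaustive-search continuous piecewise regression with
BIC-selected break count), per-pixel phase trend classification
(Increase/Decrease/No-trend at p < 0.05), the 4-phase conversion
typology (codes like `D-I-D-I`), and centroid-shift tracking of trend
directions.

## Worked example

Everything runs on synthetic scenes with known ground truth — no
downloads. A scene prescribes per-pixel (α, β, γ) surfaces, generates
climate with seasonal cycles and phase-structured drift, and drives the
NDVI anomaly process with them:

```python
from ecovuln import SynthConfig, simulate_scene, VulnerabilityModel
from ecovuln.spatial import stable_ecosystem_mask

cfg = SynthConfig(grid_rows=40, grid_cols=40, rng_seed=7)
scene = simulate_scene(cfg)
mask, _ = stable_ecosystem_mask(scene["landcover"])
results = VulnerabilityModel.from_scene(scene, mask=mask).fit()
print(results.summary())
```

```
Ecosystem vulnerability assessment (moving-window AR(1))
==========================================================
grid: 40 x 40  |  windows: 36 (5-yr length, 1-yr step)
midpoint years: 1985-2020  |  mean pixel fit rate: 100.0%

 index     mean      min      max     CV %
    EI    0.422    0.360    0.457     5.46
    SI    0.267    0.235    0.298     5.62
    RI    0.444    0.389    0.502     6.20
    VI    0.103    0.077    0.119     8.70
```

The 40-year monthly record yields 36 overlapping windows with midpoint
years 1985–2020; each row summarizes the regional yearly mean of one
index over those 36 years (CV = 100·sd/mean of the yearly series). On
this scene the prescribed north–south gradient shows up directly:
`results.multi_year_mean("VI")` rises monotonically with latitude, and
`results.regional_series()` feeds the phase detector
(`ecovuln.temporal.detect_phases`), per-pixel trend maps and centroid
tracks.

The same pipeline runs from the shell:

```sh
ecovuln run --config config.yaml --seed 7 --outdir out/
```

writing NetCDF index cubes, CSV tables (windows, regional series,
phases, conversion types, centroids, ANOVA letters) and a JSON manifest
with output hashes. Subcommands (`simulate`, `preprocess`, `assess`,
`spatial`, `temporal`, `centroids`) run prefixes of the chain.

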