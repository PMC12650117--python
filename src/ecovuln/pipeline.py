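"""End-to-end run configuration and orchestration.

One :class:`RunConfig` (YAML-serializable) ties together simulation (or
input paths), preprocessing, the windowed assessment, and the spatial
and temporal analyses; :func:`run_pipeline` executes the requested
stages and writes a manifest recording inputs, seed, version and output
hashes. Defaults reproduce the canonical configuration: 5-year windows,
1-year step, significance level 0.05.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as evio
from .model import VulnerabilityModel
from .preprocess import fill_gaps_3x3, monthly_composite_mvc, resample_bilinear
from .spatial import bin_profile, ecosystem_anova, fit_gradient, sample_ecosystems, \
    stable_ecosystem_mask
from .synthetic import SynthConfig, simulate_scene
from .temporal import centroid_track, conversion_types, detect_phases, \
    phase_trend_map, regional_series

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "assess", "spatial", "temporal",
              "centroids")


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Either ``synth`` holds synthetic-scene parameters, or the three
    ``*_path`` fields point at NetCDF cubes (plus ``landcover_path``).
    CLI flags override file values; the merged config is written next to
    the outputs. Round-trips losslessly through YAML.
    """

    outdir: str = "ecovuln_out"
    rng_seed: int = 0
    synth: dict | None = None
    ndvi_path: str | None = None
    temp_path: str | None = None
    precip_path: str | None = None
    landcover_path: str | None = None
    window_length: int = 5
    window_step: int = 1
    standardization: str = "per_month"
    min_valid_fraction: float = 0.8
    alpha: float = 0.05
    max_breaks: int = 4
    min_segment: int = 3
    centroid_weighting: str = "binary"
    n_sample_points: int = 2088
    lat_bin_deg: float = 1.0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self),
                                       sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def synth_config(self) -> SynthConfig:
        kw = dict(self.synth or {})
        kw.setdefault("rng_seed", self.rng_seed)
        for key in ("phase_breaks", "phase_slopes", "constant_params"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return SynthConfig(**kw)


def run_pipeline(config: RunConfig,
                 stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Execute the pipeline stages and return the manifest dict.

    Stage chain: simulate (optional) → preprocess → assess → spatial →
    temporal → centroids. Later stages pull their inputs from earlier
    ones in the same run; a failure aborts with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    ctx: dict = {}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, ctx, outputs)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") \
                from exc
    outputs.append(config.to_yaml(outdir / "config_effective.yaml"))
    evio.write_manifest(outdir, dataclasses.asdict(config), outputs)
    manifest = json.loads((outdir / "manifest.json").read_text())
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, ctx: dict, outputs: list) -> None:
    outdir = Path(config.outdir)
    if config.synth is None and config.ndvi_path is not None:
        log.info("simulate: input paths configured, nothing to simulate")
        return
    scfg = config.synth_config()
    scene = simulate_scene(scfg)
    ctx.update(scene)
    ctx["synth_config"] = scfg
    outputs.append(evio.write_cube(scene["ndvi"], outdir / "ndvi.nc", "ndvi"))
    outputs.append(evio.write_cube(scene["temp"], outdir / "temp.nc", "temp"))
    outputs.append(evio.write_cube(scene["precip"], outdir / "precip.nc",
                                   "precip"))
    outputs.append(evio.write_landcover(scene["landcover"], scfg.grid,
                                        outdir / "landcover.nc"))
    outputs.append(evio.write_truth(scene["truth"], scfg.grid,
                                    outdir / "truth.nc",
                                    dataclasses.asdict(scfg)))
    log.info("simulate: scene %dx%d, %s–%s", scfg.grid_rows, scfg.grid_cols,
             scfg.start_year, scfg.end_year)


def _load_inputs(config: RunConfig, ctx: dict) -> None:
    if "ndvi" in ctx:
        return
    if not (config.ndvi_path and config.temp_path and config.precip_path):
        raise ValueError("no simulated scene in context and no input paths "
                         "configured")
    ctx["ndvi"] = evio.read_cube(config.ndvi_path, "ndvi")
    ctx["temp"] = evio.read_cube(config.temp_path, "temp")
    ctx["precip"] = evio.read_cube(config.precip_path, "precip")
    if config.landcover_path:
        ctx["landcover"], _ = evio.read_landcover(config.landcover_path)


def _stage_preprocess(config: RunConfig, ctx: dict, outputs: list) -> None:
    outdir = Path(config.outdir)
    _load_inputs(config, ctx)
    ndvi = ctx["ndvi"]
    if ndvi.cadence == "biweekly":
        ndvi = monthly_composite_mvc(ndvi)
    ndvi = fill_gaps_3x3(ndvi)
    if ndvi.grid.shape != ctx["temp"].grid.shape:
        # vegetation is upsampled onto the climate grid, never the reverse
        ndvi = resample_bilinear(ndvi, ctx["temp"].grid)
    ctx["ndvi_pre"] = ndvi
    outputs.append(evio.write_cube(ndvi, outdir / "ndvi_preprocessed.nc",
                                   "ndvi"))


def _stage_assess(config: RunConfig, ctx: dict, outputs: list) -> None:
    outdir = Path(config.outdir)
    _load_inputs(config, ctx)
    ndvi = ctx.get("ndvi_pre", ctx["ndvi"])
    mask = None
    if ctx.get("landcover") is not None:
        mask, _ = stable_ecosystem_mask(ctx["landcover"])
        ctx["stable_mask"] = mask
    model = VulnerabilityModel(
        ndvi, ctx["temp"], ctx["precip"], window_length=config.window_length,
        window_step=config.window_step,
        standardization=config.standardization,
        min_valid_fraction=config.min_valid_fraction, mask=mask)
    results = model.fit()
    ctx["results"] = results
    ds = results.indices.to_dataset()
    path = outdir / "indices.nc"
    ds.to_netcdf(path, engine="scipy")
    outputs.append(path)
    outputs.append(evio.write_windows_csv(model.windows,
                                          outdir / "windows.csv"))
    scaling = outdir / "scaling_constants.json"
    scaling.write_text(json.dumps(results.indices.scaling_log, indent=2))
    outputs.append(scaling)


def _stage_spatial(config: RunConfig, ctx: dict, outputs: list) -> None:
    outdir = Path(config.outdir)
    results = ctx["results"]
    lat = results.indices.grid.latitude_raster()
    rows = []
    for index in ("EI", "SI", "RI", "VI"):
        surface = results.multi_year_mean(index)
        prof = bin_profile(surface, lat, config.lat_bin_deg,
                           variable="latitude", index=index)
        centers, means = prof.occupied()
        for c, m, n in zip(centers, means,
                           prof.bin_counts[prof.bin_counts > 0]):
            rows.append({"index": index, "variable": "latitude",
                         "bin_center": c, "mean": m, "count": int(n)})
        if len(centers) >= 3:
            g = fit_gradient(prof, "linear")
            rows.append({"index": index, "variable": "latitude_slope",
                         "bin_center": np.nan, "mean": g.slopes[0],
                         "count": len(centers)})
    path = outdir / "profiles.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    outputs.append(path)

    if ctx.get("landcover") is not None:
        samples = sample_ecosystems(results.indices, ctx["landcover"],
                                    config.n_sample_points, config.rng_seed)
        ctx["samples"] = samples
        tables = []
        for index in ("EI", "SI", "RI", "VI"):
            try:
                tables.append(ecosystem_anova(samples, index,
                                              alpha=config.alpha).to_frame())
            except ValueError as exc:
                log.warning("ANOVA skipped for %s: %s", index, exc)
        if tables:
            apath = outdir / "ecosystem_anova.csv"
            pd.concat(tables).to_csv(apath, index=False)
            outputs.append(apath)


def _stage_temporal(config: RunConfig, ctx: dict, outputs: list) -> None:
    outdir = Path(config.outdir)
    results = ctx["results"]
    reg = regional_series(results.indices, ctx.get("stable_mask"))
    rpath = outdir / "regional_series.csv"
    reg.to_frame().to_csv(rpath, index=False)
    outputs.append(rpath)

    # a short series supports fewer breaks: every phase needs min_segment yrs
    max_breaks = min(config.max_breaks,
                     len(reg.years) // config.min_segment - 1)
    seg = detect_phases(reg.years, reg.mean_series("VI"),
                        max_breaks=max(max_breaks, 0),
                        min_segment=config.min_segment)
    ctx["segmentation"] = seg
    spath = outdir / "phases.csv"
    pd.DataFrame(seg.phases).to_csv(spath, index=False)
    outputs.append(spath)

    maps = [phase_trend_map(results.indices, (p["start"], p["end"]),
                            alpha=config.alpha) for p in seg.phases]
    ctx["trend_maps"] = maps
    conv = conversion_types(maps, ctx.get("stable_mask"))
    ctx["conversion"] = conv
    cpath = outdir / "conversion_types.csv"
    conv.proportions.to_csv(cpath, index=False)
    outputs.append(cpath)


def _stage_centroids(config: RunConfig, ctx: dict, outputs: list) -> None:
    outdir = Path(config.outdir)
    maps = ctx["trend_maps"]
    rows = []
    for direction in ("I", "D"):
        track = centroid_track(maps, direction,
                               weighting=config.centroid_weighting)
        for k, cen in enumerate(track.centroids):
            row = {"direction": direction, "phase_start": track.phases[k][0],
                   "phase_end": track.phases[k][1],
                   "lat": cen[0] if cen else np.nan,
                   "lon": cen[1] if cen else np.nan}
            if k > 0:
                row.update(track.displacements[k - 1])
            rows.append(row)
    path = outdir / "centroids.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    outputs.append(path)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "assess": _stage_assess,
    "spatial": _stage_spatial,
    "temporal": _stage_temporal,
    "centroids": _stage_centroids,
}
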