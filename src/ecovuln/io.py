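"""File formats: NetCDF cubes, CSV tables, JSON sidecars and manifests.

Cubes are stored as classic NetCDF (via xarray's scipy backend) with a
CF-style time axis and the grid georeference carried in global
attributes. NaN is written as the declared ``_FillValue``. Everything
tabular (window tables, regional series, profiles, ANOVA letters,
conversion types, centroid tracks) goes to CSV; run provenance goes to
a JSON manifest with SHA-256 hashes of every output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import Grid, MonthlyCube
from .preprocess import MovingWindow
from .synthetic import LANDCOVER_CLASSES, LandcoverMaps, TruthFields

__all__ = [
    "write_cube", "read_cube", "write_landcover", "read_landcover",
    "write_truth", "read_truth", "write_windows_csv", "manifest_entry",
    "write_manifest",
]

_GRID_ATTRS = ("origin_lat", "origin_lon", "cell_size", "crs")


def _grid_attrs(grid: Grid) -> dict:
    return {"origin_lat": grid.origin_lat, "origin_lon": grid.origin_lon,
            "cell_size": grid.cell_size, "crs": grid.crs}


def _grid_from_attrs(attrs: dict, n_rows: int, n_cols: int) -> Grid:
    missing = [a for a in _GRID_ATTRS if a not in attrs]
    if missing:
        raise ValueError(f"file lacks grid metadata: missing {missing} "
                         "(no CRS/georeference)")
    return Grid(n_rows, n_cols, float(attrs["origin_lat"]),
                float(attrs["origin_lon"]), float(attrs["cell_size"]),
                str(attrs["crs"]))


def write_cube(cube: MonthlyCube, path: str | Path,
               variable: str = "value") -> Path:
    """Write a cube to classic NetCDF; NaN becomes the file's nodata."""
    path = Path(path)
    if cube.cadence == "monthly":
        times = cube.time.to_timestamp()
    else:
        times = cube.time
    da = xr.DataArray(cube.values, dims=("time", "row", "col"),
                      coords={"time": times, "lat": ("row", cube.grid.lats),
                              "lon": ("col", cube.grid.lons)},
                      name=variable, attrs={"units": cube.units})
    ds = da.to_dataset()
    ds.attrs.update(_grid_attrs(cube.grid))
    ds.attrs["cadence"] = cube.cadence
    for k, v in cube.attrs.items():
        if np.isscalar(v):
            ds.attrs[f"x_{k}"] = v
    enc = {variable: {"_FillValue": np.float64(-9999.0)}}
    ds.to_netcdf(path, engine="scipy", encoding=enc)
    return path


def read_cube(path: str | Path, variable: str = "value") -> MonthlyCube:
    """Read a cube written by :func:`write_cube`.

    Raises a clear error naming the missing field when the time axis or
    the grid georeference is absent.
    """
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not in {path}")
        if "time" not in ds.coords:
            raise ValueError(f"{path} lacks a 'time' coordinate")
        da = ds[variable].load()
        cadence = str(ds.attrs.get("cadence", "monthly"))
        n_rows, n_cols = da.shape[1], da.shape[2]
        grid = _grid_from_attrs(ds.attrs, n_rows, n_cols)
        times = pd.DatetimeIndex(da["time"].values)
        if cadence == "monthly":
            time_idx = times.to_period("M")
        else:
            time_idx = times
        attrs = {k[2:]: v for k, v in ds.attrs.items() if k.startswith("x_")}
        return MonthlyCube(da.values.astype(np.float64), time_idx, grid,
                           cadence=cadence,
                           units=str(da.attrs.get("units", "")), attrs=attrs)


def write_landcover(lc: LandcoverMaps, grid: Grid, path: str | Path) -> Path:
    path = Path(path)
    da = xr.DataArray(lc.maps.astype(np.int32), dims=("year", "row", "col"),
                      coords={"year": lc.years}, name="landcover")
    ds = da.to_dataset()
    ds.attrs.update(_grid_attrs(grid))
    ds.attrs["classes"] = json.dumps(list(LANDCOVER_CLASSES))
    ds.to_netcdf(path, engine="scipy")
    return path


def read_landcover(path: str | Path) -> tuple[LandcoverMaps, Grid]:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        da = ds["landcover"].load()
        grid = _grid_from_attrs(ds.attrs, da.shape[1], da.shape[2])
        years = [int(y) for y in da["year"].values]
        return LandcoverMaps(years, da.values.astype(np.int16)), grid


def write_truth(truth: TruthFields, grid: Grid, path: str | Path,
                config_json: dict | None = None) -> Path:
    """Persist truth surfaces as a NetCDF plus a JSON sidecar of config."""
    path = Path(path)
    ds = xr.Dataset(
        {name: (("row", "col"), getattr(truth, name).astype(np.float64))
         for name in ("alpha_true", "beta_true", "gamma_true", "noise_sd")}
        | {"landcover_true": (("row", "col"),
                              truth.landcover_true.astype(np.int32))})
    ds.attrs.update(_grid_attrs(grid))
    ds.to_netcdf(path, engine="scipy")
    if config_json is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(config_json, indent=2, default=str))
    return path


def read_truth(path: str | Path) -> TruthFields:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        return TruthFields(
            ds["alpha_true"].values, ds["beta_true"].values,
            ds["gamma_true"].values, ds["noise_sd"].values,
            ds["landcover_true"].values.astype(np.int16))


def write_windows_csv(windows: list[MovingWindow], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([{"start": w.start_year, "end": w.end_year,
                   "midpoint": w.midpoint_year, "n_months": w.n_months}
                  for w in windows]).to_csv(path, index=False)
    return path


def manifest_entry(path: str | Path) -> dict:
    p = Path(path)
    digest = hashlib.sha256(p.read_bytes()).hexdigest()
    return {"path": p.name, "sha256": digest, "bytes": p.stat().st_size}


def write_manifest(outdir: str | Path, config: dict,
                   outputs: list[str | Path]) -> Path:
    import ecovuln
    outdir = Path(outdir)
    manifest = {
        "package_version": getattr(ecovuln, "__version__", "unknown"),
        "config": config,
        "outputs": [manifest_entry(p) for p in sorted(map(str, outputs))],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
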