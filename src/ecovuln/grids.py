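"""Georeferenced grid and raster-cube containers.

The working currency of the pipeline is the :class:`MonthlyCube`: a
``(time, row, col)`` stack of monthly values (NDVI, temperature or
precipitation) on a regular lat/lon grid. Missing values are NaN
internally; file formats translate NaN to their declared nodata value.

Grid convention: cell-centre coordinates, row 0 at the northern edge,
column 0 at the western edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Grid", "MonthlyCube", "month_index"]


@dataclass(frozen=True)
class Grid:
    """Regular geographic grid, cell-centre registered, row 0 north.

    Parameters
    ----------
    n_rows, n_cols : int
        Cell counts; must be positive.
    origin_lat, origin_lon : float
        Latitude/longitude of the centre of cell ``(0, 0)`` in degrees.
        Latitude decreases with row index.
    cell_size : float
        Cell edge length in degrees, > 0.
    crs : str
        Coordinate reference system identifier (informational).
    """

    n_rows: int
    n_cols: int
    origin_lat: float = 34.0
    origin_lon: float = 98.0
    cell_size: float = 0.05
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lats(self) -> np.ndarray:
        """Latitude of each row's cell centres (descending)."""
        return self.origin_lat - np.arange(self.n_rows) * self.cell_size

    @property
    def lons(self) -> np.ndarray:
        """Longitude of each column's cell centres (ascending)."""
        return self.origin_lon + np.arange(self.n_cols) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return 2-D ``(lat, lon)`` arrays of cell-centre coordinates."""
        return np.meshgrid(self.lats, self.lons, indexing="ij")

    def latitude_raster(self) -> np.ndarray:
        return self.cell_centers()[0]

    def longitude_raster(self) -> np.ndarray:
        return self.cell_centers()[1]


def month_index(start_year: int, end_year: int) -> pd.PeriodIndex:
    """Monthly PeriodIndex covering Jan ``start_year`` .. Dec ``end_year``."""
    return pd.period_range(f"{start_year}-01", f"{end_year}-12", freq="M")


@dataclass
class MonthlyCube:
    """A time-stacked raster of one variable.

    ``values`` has shape ``(len(time), n_rows, n_cols)``; NaN marks
    missing data. ``time`` is a monthly :class:`pandas.PeriodIndex` for
    monthly cadence, or a :class:`pandas.DatetimeIndex` (days 1 and 16 of
    each month) for biweekly cadence.
    """

    values: np.ndarray
    time: pd.PeriodIndex | pd.DatetimeIndex
    grid: Grid
    cadence: str = "monthly"
    units: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, row, col)")
        if self.values.shape[0] != len(self.time):
            raise ValueError("time axis length mismatch")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError("spatial dims inconsistent with grid")
        if self.cadence not in ("monthly", "biweekly"):
            raise ValueError(f"unknown cadence {self.cadence!r}")
        if self.cadence == "monthly":
            if not isinstance(self.time, pd.PeriodIndex):
                raise TypeError("monthly cube requires a PeriodIndex time axis")
            if len(self.time) > 1:
                steps = np.diff(self.time.asi8)
                if not np.all(steps == 1):
                    raise ValueError(
                        "monthly time index must be strictly increasing with "
                        "one entry per month and no duplicates"
                    )
        else:
            if not self.time.is_monotonic_increasing or self.time.has_duplicates:
                raise ValueError("biweekly time index must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    def month_labels(self) -> pd.PeriodIndex:
        """Year-month label of every time step (many-to-one for biweekly)."""
        if isinstance(self.time, pd.PeriodIndex):
            return self.time
        return self.time.to_period("M")

    def copy_with(self, values: np.ndarray, **kwargs) -> "MonthlyCube":
        base = dict(
            values=values,
            time=self.time,
            grid=self.grid,
            cadence=self.cadence,
            units=self.units,
            attrs=dict(self.attrs),
        )
        base.update(kwargs)
        return MonthlyCube(**base)

    def align_check(self, other: "MonthlyCube") -> None:
        """Raise if the two cubes are not on the same grid and time axis."""
        if self.grid.shape != other.grid.shape:
            raise ValueError("cubes are on different grids")
        if len(self.time) != len(other.time) or not (self.time == other.time).all():
            raise ValueError("cubes have different time axes")


def _replace(grid: Grid, **kw) -> Grid:
    return replace(grid, **kw)
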