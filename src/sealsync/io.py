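"""Readers and writers for the pipeline's plain-text formats.

Counts travel as tidy CSV (species, year, count, observed_flag); SIC grids
as CF-style netCDF (dims time/lat/lon, variable ``sic`` in percent, written
with the netCDF3 backend) or an equivalent long CSV (date, lat, lon, sic).
Missing survey years are represented explicitly — the year axis stays
contiguous and the observation mask records the gaps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .phenology import SICGrid
from .synthetic import CountMatrix

__all__ = [
    "write_counts",
    "read_counts",
    "write_covariates",
    "read_covariates",
    "write_sic_netcdf",
    "read_sic_netcdf",
    "write_sic_csv",
    "read_sic_csv",
]


def write_counts(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path, index=False)


def read_counts(path) -> CountMatrix:
    """Read a tidy counts CSV into a CountMatrix.

    Duplicate (species, year) rows, negative observed counts and
    non-contiguous year axes are rejected with specific errors.  Years
    absent from the file become unobserved cells so indices stay aligned.
    """
    df = pd.read_csv(path)
    required = {"species", "year", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts file must have columns {sorted(required)}")
    dup = df.duplicated(subset=["species", "year"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicated (species, year) row: {row['species']}, {int(row['year'])}")
    if "observed_flag" not in df.columns:
        df["observed_flag"] = 1
    obs_rows = df[df.observed_flag == 1]
    if (obs_rows["count"] < 0).any():
        bad = obs_rows[obs_rows["count"] < 0].iloc[0]
        raise ValueError(f"negative count for {bad['species']} in {int(bad['year'])}")
    species = sorted(df.species.unique())
    y0, y1 = int(df.year.min()), int(df.year.max())
    years = np.arange(y0, y1 + 1)
    S, T = len(species), len(years)
    y = np.zeros((S, T), dtype=np.int64)
    observed = np.zeros((S, T), dtype=bool)
    sp_idx = {sp: i for i, sp in enumerate(species)}
    for _, row in df.iterrows():
        i, j = sp_idx[row.species], int(row.year) - y0
        y[i, j] = int(row["count"])
        observed[i, j] = bool(row.observed_flag)
    counts = CountMatrix(species=species, years=years, y=y, observed=observed)
    counts.validate()
    return counts


def write_covariates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def _grid_to_dataset(grid: SICGrid) -> xr.Dataset:
    return xr.Dataset(
        {"sic": (("time", "lat", "lon"), grid.sic,
                 {"units": "percent", "long_name": "sea ice concentration"})},
        coords={
            "time": grid.dates.astype("datetime64[ns]"),
            "lat": ("lat", grid.lat, {"units": "degrees_north"}),
            "lon": ("lon", grid.lon, {"units": "degrees_east"}),
        },
    )


def write_sic_netcdf(grid: SICGrid, path) -> None:
    _grid_to_dataset(grid).to_netcdf(path, engine="scipy")


def read_sic_netcdf(path) -> SICGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        dates = ds.time.values.astype("datetime64[D]")
        if dates.size > 1 and not np.all(np.diff(dates).astype(int) == 1):
            raise ValueError("time axis is not daily")
        return SICGrid(dates=dates, lat=ds.lat.values.copy(),
                       lon=ds.lon.values.copy(), sic=ds.sic.values.copy())


def write_sic_csv(grid: SICGrid, path) -> None:
    ds = _grid_to_dataset(grid)
    df = ds.sic.to_dataframe().reset_index()
    df["time"] = df["time"].dt.strftime("%Y-%m-%d")
    df.rename(columns={"time": "date"}).to_csv(path, index=False)


def read_sic_csv(path) -> SICGrid:
    df = pd.read_csv(path)
    for col in ("date", "lat", "lon", "sic"):
        if col not in df.columns:
            raise ValueError(f"long SIC CSV needs column {col!r}")
    dates = np.sort(df.date.unique()).astype("datetime64[D]")
    if dates.size > 1 and not np.all(np.diff(dates).astype(int) == 1):
        raise ValueError("time axis is not daily")
    lat = np.sort(df.lat.unique())
    lon = np.sort(df.lon.unique())
    pivot = df.set_index(["date", "lat", "lon"]).sic.sort_index()
    sic = pivot.to_numpy().reshape(dates.size, lat.size, lon.size)
    return SICGrid(dates=dates, lat=lat, lon=lon, sic=sic)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
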