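"""netCDF I/O in the published convention, plus grid harmonization.

Merged yearly files follow the naming convention ``Merged.Tveg.<year>.nc``
with variables ``lat`` (latitude, ascending), ``lon`` (longitude,
[-180, 180)), ``day`` (day of the year) and ``Ec`` (vegetation
transpiration, mm day^-1).  Reading normalises coordinates to those
conventions and masks fill values; writing prefers whatever netCDF engine
xarray finds and falls back to the scipy (netCDF-3) backend, which is
always available.
"""

from __future__ import annotations

import calendar
from pathlib import Path

import numpy as np
import xarray as xr

__all__ = ["read_product", "write_merged", "read_merged", "regrid", "save_cube"]


def _to_netcdf(ds: xr.Dataset, path: Path) -> None:
    try:
        ds.to_netcdf(path)
    except (ValueError, ModuleNotFoundError):
        ds.to_netcdf(path, engine="scipy")


def save_cube(cube: xr.DataArray, path: str | Path, variable: str = "Ec") -> Path:
    """Write a (time, lat, lon) cube as a netCDF file with the given variable."""
    path = Path(path)
    ds = cube.rename(variable).to_dataset()
    _to_netcdf(ds, path)
    return path


def read_product(path: str | Path, variable: str) -> xr.DataArray:
    """Read one product variable and normalise its coordinates.

    Latitude is flipped ascending when needed; longitude is wrapped into
    [-180, 180) and sorted; fill values and NaNs become missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such product file: {path}")
    try:
        ds = xr.open_dataset(path)
    except ValueError:
        ds = xr.open_dataset(path, engine="scipy")
    if variable not in ds:
        available = sorted(ds.data_vars)
        raise KeyError(
            f"{path}: variable {variable!r} not found; available: {available}"
        )
    da = ds[variable].load()
    ds.close()
    if "lat" in da.dims and da["lat"].size > 1 and da["lat"].values[0] > da["lat"].values[-1]:
        da = da.isel(lat=slice(None, None, -1))
    if "lon" in da.dims:
        lon = da["lon"].values
        if lon.max() >= 180.0:
            da = da.assign_coords(lon=((lon + 180.0) % 360.0) - 180.0).sortby("lon")
    fill = da.attrs.get("_FillValue", da.encoding.get("_FillValue"))
    if fill is not None and np.isfinite(fill):
        da = da.where(da != fill)
    return da


def write_merged(
    cube: xr.DataArray,
    out_dir: str | Path,
    year: int,
    overwrite: bool = False,
    daily: bool = False,
) -> Path:
    """Write one calendar year of merged transpiration as Merged.Tveg.<year>.nc.

    The file holds variables lat, lon, day and Ec.  By default the cube's
    native time steps are written with their day-of-year stamps; with
    ``daily=True`` each native (e.g. 8-day) value is repeated onto every
    constituent day so the day axis spans the full year (366 on leap years).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"Merged.Tveg.{year}.nc"
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")

    if "time" not in cube.dims:
        raise ValueError("cube must have a time dimension")
    time_vals = cube["time"].values
    if np.issubdtype(np.asarray(time_vals).dtype, np.datetime64):
        days = cube["time"].dt.dayofyear.values.astype(np.int32)
    else:
        days = np.asarray(time_vals).astype(np.int32)
        if days.min() < 1:
            days = days - days.min() + 1  # 0-based step index -> day of year

    values = cube.transpose("time", "lat", "lon").values
    if daily:
        n_days = 366 if calendar.isleap(year) else 365
        full = np.full((n_days, values.shape[1], values.shape[2]), np.nan)
        bounds = np.append(days, n_days + 1)
        for k in range(len(days)):
            full[bounds[k] - 1 : bounds[k + 1] - 1] = values[k]
        values, days = full, np.arange(1, n_days + 1, dtype=np.int32)

    ds = xr.Dataset(
        {"Ec": (("day", "lat", "lon"), values)},
        coords={
            "day": ("day", days),
            "lat": ("lat", np.asarray(cube["lat"].values, dtype=float)),
            "lon": ("lon", np.asarray(cube["lon"].values, dtype=float)),
        },
    )
    ds["lat"].attrs["standard_name"] = "latitude"
    ds["lon"].attrs["standard_name"] = "longitude"
    ds["day"].attrs["standard_name"] = "day of the year"
    ds["Ec"].attrs.update(
        {"standard_name": "vegetation transpiration", "units": "mm day-1"}
    )
    _to_netcdf(ds, path)
    return path


def read_merged(path: str | Path) -> xr.Dataset:
    """Read back a merged yearly file."""
    try:
        return xr.open_dataset(path).load()
    except ValueError:
        return xr.open_dataset(path, engine="scipy").load()


def regrid(
    cube: xr.DataArray,
    target_lat: np.ndarray,
    target_lon: np.ndarray,
    method: str = "bilinear",
) -> xr.DataArray:
    """Regrid onto target cell centers by bilinear or nearest interpolation.

    Bilinear is exact for fields linear in lat/lon; cells with no valid
    source neighbourhood come out missing.  Raises when the extents are
    disjoint.
    """
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)
    lat, lon = cube["lat"].values, cube["lon"].values
    if target_lat.max() < lat.min() or target_lat.min() > lat.max():
        raise ValueError("target latitude range is disjoint from the source grid")
    if target_lon.max() < lon.min() or target_lon.min() > lon.max():
        raise ValueError("target longitude range is disjoint from the source grid")
    if method == "bilinear":
        return cube.interp(lat=target_lat, lon=target_lon, method="linear")
    if method == "nearest":
        return cube.sel(lat=target_lat, lon=target_lon, method="nearest").assign_coords(
            lat=target_lat, lon=target_lon
        )
    raise ValueError(f"unknown regrid method {method!r}")
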