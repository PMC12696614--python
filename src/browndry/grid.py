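"""Shared grid definition, annual-field container conventions and NetCDF I/O.

Every stage of the pipeline exchanges annual gridded fields as
:class:`xarray.DataArray` objects with dimensions ``(lat, lon, year)``:
``lat``/``lon`` are regular cell-center coordinates in degrees, ``year`` is a
run of consecutive calendar years, missing data are NaN, and physical units
live in ``attrs["units"]``.  This module holds the :class:`GridSpec` that
validates those axes, latitude-cosine area weights, and NetCDF helpers built
on xarray's scipy backend (classic NetCDF3, so integer variables are stored
as 32-bit and booleans as bytes).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = [
    "GridSpec",
    "annual_grid",
    "validate_annual_grid",
    "cos_lat_weights",
    "save_dataset",
    "load_dataset",
]


class GridError(ValueError):
    """Invalid grid axes or a field that does not match its grid."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid with an annual time axis.

    Parameters
    ----------
    lats, lons
        Cell-center coordinates in degrees north / east.  Latitudes must lie
        in [-90, 90], longitudes in [-180, 180).
    years
        Strictly consecutive calendar years (at least 10).
    """

    lats: np.ndarray
    lons: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        lats = np.asarray(self.lats, dtype=float)
        lons = np.asarray(self.lons, dtype=float)
        years = np.asarray(self.years, dtype=int)
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)
        object.__setattr__(self, "years", years)
        if lats.ndim != 1 or lons.ndim != 1 or years.ndim != 1:
            raise GridError("lats, lons and years must be one-dimensional")
        if lats.size * lons.size < 2:
            raise GridError("grid needs at least 2 cells")
        if years.size < 10:
            raise GridError("grid needs at least 10 years")
        if np.any(np.diff(years) != 1):
            raise GridError("years must be strictly consecutive integers")
        if np.any((lats < -90) | (lats > 90)):
            raise GridError("latitudes must lie within [-90, 90]")
        if np.any((lons < -180) | (lons >= 180)):
            raise GridError("longitudes must lie within [-180, 180)")

    @classmethod
    def regular(
        cls,
        nlat: int = 20,
        nlon: int = 30,
        year_start: int = 1982,
        year_end: int = 2020,
        lat_bounds: tuple[float, float] = (-55.0, 70.0),
        lon_bounds: tuple[float, float] = (-180.0, 180.0),
    ) -> "GridSpec":
        """Evenly spaced cell centers; the default mirrors the desk-scale
        study domain (20 x 30 cells, 1982-2020)."""
        lat_edges = np.linspace(*lat_bounds, nlat + 1)
        lon_edges = np.linspace(*lon_bounds, nlon + 1)
        return cls(
            lats=0.5 * (lat_edges[:-1] + lat_edges[1:]),
            lons=0.5 * (lon_edges[:-1] + lon_edges[1:]),
            years=np.arange(year_start, year_end + 1),
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.lats.size, self.lons.size, self.years.size)

    def coords(self) -> dict[str, np.ndarray]:
        return {"lat": self.lats, "lon": self.lons, "year": self.years}


def annual_grid(
    grid: GridSpec, values: np.ndarray, name: str, units: str = ""
) -> xr.DataArray:
    """Wrap raw ``(lat, lon, year)`` values as the shared annual-field type."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise GridError(
            f"values shape {values.shape} does not match grid {grid.shape}"
        )
    return xr.DataArray(
        values,
        coords=grid.coords(),
        dims=("lat", "lon", "year"),
        name=name,
        attrs={"units": units},
    )


def validate_annual_grid(da: xr.DataArray, nonnegative: bool = False) -> None:
    """Check the shared-field contract (dims, coord sanity, optional sign)."""
    if tuple(da.dims) != ("lat", "lon", "year"):
        raise GridError(f"expected dims (lat, lon, year), got {da.dims}")
    GridSpec(da["lat"].values, da["lon"].values, da["year"].values)
    if nonnegative and bool((da < 0).any()):
        raise GridError(f"{da.name or 'field'} has negative values")


def cos_lat_weights(lats: np.ndarray | xr.DataArray) -> xr.DataArray:
    """Relative cell areas for a regular grid: cosine of center latitude."""
    lat = np.asarray(getattr(lats, "values", lats), dtype=float)
    return xr.DataArray(np.cos(np.deg2rad(lat)), coords={"lat": lat}, dims=("lat",))


# ---------------------------------------------------------------------------
# NetCDF I/O (scipy backend, classic format)

_NC3_CASTS = {
    np.dtype("int64"): np.int32,
    np.dtype("uint64"): np.int32,
    np.dtype("uint32"): np.int32,
    np.dtype("bool"): np.int8,
}


def _nc3_safe(ds: xr.Dataset) -> xr.Dataset:
    ds = ds.copy()
    for key in list(ds.variables):
        var = ds[key]
        cast = _NC3_CASTS.get(var.dtype)
        if cast is not None:
            attrs = dict(var.attrs)
            if var.dtype == np.dtype("bool"):
                attrs.setdefault("flag_values", "0 1")
                attrs.setdefault("flag_meanings", "false true")
            if key in ds.coords:
                ds = ds.assign_coords({key: var.astype(cast)})
                ds[key].attrs.update(attrs)
            else:
                ds[key] = var.astype(cast)
                ds[key].attrs.update(attrs)
    return ds


def save_dataset(ds: xr.Dataset | xr.DataArray, path, **attrs) -> None:
    """Write a dataset (or a single field) as classic NetCDF.

    Extra keyword arguments become global attributes, e.g. the run's config
    hash for provenance.
    """
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "value")
    ds = _nc3_safe(ds)
    ds.attrs.update({k: str(v) for k, v in attrs.items()})
    ds.to_netcdf(path, engine="scipy")


def load_dataset(path) -> xr.Dataset:
    """Read a NetCDF file written by :func:`save_dataset` (values in memory)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def config_hash(payload: str) -> str:
    """Short stable hash used to stamp output files with their configuration."""
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]
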