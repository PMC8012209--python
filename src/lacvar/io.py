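"""CF-convention netCDF reading and writing for monthly fields.

Geometry comes from ``lat``/``lon`` coordinate variables; ``lat_bnds`` /
``lon_bnds``, when present, take precedence over the midpoint-bounds default
for the area computation.  Units are normalized at read time per an
explicit map (K -> degC offset; kg m-2 s-1 -> gC m-2 month-1 for carbon
fluxes using a 30-day month, recorded in metadata).
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grid import EARTH_RADIUS_M, GridGeometry, MonthlyField

__all__ = ["read_cf_monthly", "write_cf_monthly", "areas_from_bounds"]

SECONDS_PER_MONTH = 30.0 * 86400.0  # nominal month for rate conversion


def areas_from_bounds(lat_bnds: np.ndarray, lon_bnds: np.ndarray) -> np.ndarray:
    """Spherical cell areas (m^2) from explicit CF bounds arrays (n, 2)."""
    sin_lat = np.sin(np.deg2rad(np.asarray(lat_bnds, float)))
    band = np.abs(sin_lat[:, 1] - sin_lat[:, 0])
    dlon = np.abs(np.deg2rad(np.asarray(lon_bnds, float)))
    dlon = np.abs(dlon[:, 1] - dlon[:, 0])
    return EARTH_RADIUS_M**2 * np.outer(band, dlon)


def _convert_units(values: np.ndarray, units: str, target: str | None
                   ) -> tuple[np.ndarray, str]:
    if target is None or units == target:
        return values, units
    key = (units, target)
    if key == ("K", "degC"):
        return values - 273.15, "degC"
    if key == ("kg m-2 s-1", "gC m-2 month-1"):
        return values * 1000.0 * SECONDS_PER_MONTH, "gC m-2 month-1"
    if key == ("Pa", "kPa"):
        return values * 1e-3, "kPa"
    raise ValueError(f"no unit conversion registered for {units!r} -> {target!r}")


def read_cf_monthly(path, var_names: list[str],
                    units_map: dict[str, str] | None = None
                    ) -> tuple[dict[str, MonthlyField], GridGeometry]:
    """Read monthly fields and grid geometry from a CF netCDF file.

    ``units_map`` maps variable name to the target units it should be
    converted to on read (e.g. ``{"T": "degC"}``).
    """
    units_map = units_map or {}
    with xr.open_dataset(path, decode_times=True) as ds:
        ds = ds.load()
    for v in var_names:
        if v not in ds:
            raise KeyError(f"variable {v!r} missing from {path}")
    lat = ds["lat"].values
    lon = ds["lon"].values
    area = None
    if "lat_bnds" in ds and "lon_bnds" in ds:
        area = areas_from_bounds(ds["lat_bnds"].values, ds["lon_bnds"].values)
    mask = ds["land_mask"].values.astype(bool) if "land_mask" in ds else None
    geo = GridGeometry(lat, lon, cell_area=area, land_mask=mask)
    try:
        times = ds.indexes["time"]
        years = np.asarray([t.year for t in times], int)
        months = np.asarray([t.month for t in times], int)
    except (KeyError, AttributeError) as exc:
        raise ValueError(f"cannot decode time axis of {path}: {exc}") from exc
    code = years * 12 + months - 1
    if code.size > 1 and not np.all(np.diff(code) == 1):
        raise ValueError("time axis not contiguous")
    fields = {}
    for v in var_names:
        vals = ds[v].values.astype(float)
        units = str(ds[v].attrs.get("units", ""))
        vals, units = _convert_units(vals, units, units_map.get(v))
        if not units:
            raise ValueError(f"variable {v!r} has no units attribute")
        fields[v] = MonthlyField(geo, years, months, vals, units=units, name=v)
    return fields, geo


def write_cf_monthly(path, fields: dict[str, MonthlyField],
                     attrs: dict | None = None) -> None:
    """Write monthly fields sharing one geometry/calendar to CF netCDF."""
    first = next(iter(fields.values()))
    geo = first.geometry
    time = np.array(
        [np.datetime64(f"{y:04d}-{m:02d}-15")
         for y, m in zip(first.years, first.months)],
        dtype="datetime64[ns]",
    )
    data = {}
    for name, f in fields.items():
        if not f.geometry.same_grid(geo):
            raise ValueError(f"field {name!r} on a different grid")
        data[name] = xr.DataArray(
            f.values, dims=("time", "lat", "lon"),
            coords={"time": time, "lat": geo.lat_centers,
                    "lon": geo.lon_centers},
            attrs={"units": f.units, "long_name": f.name or name},
        )
    ds = xr.Dataset(data)
    ds["land_mask"] = xr.DataArray(geo.land_mask.astype("i1"),
                                   dims=("lat", "lon"))
    ds["cell_area"] = xr.DataArray(geo.cell_area, dims=("lat", "lon"),
                                   attrs={"units": "m2"})
    ds.lat.attrs.update(units="degrees_north", standard_name="latitude")
    ds.lon.attrs.update(units="degrees_east", standard_name="longitude")
    ds.attrs.update(Conventions="CF-1.8", **(attrs or {}))
    ds.to_netcdf(path)
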