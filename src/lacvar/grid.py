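"""Spatial data model: grid geometry, area weighting, masking, conservative
aggregation and region means.

All gridded data in this package live on a regular lat/lon grid with
cell-center registration.  Cell areas are computed on a sphere from cell
bounds (proportional to ``dlon * (sin(lat_top) - sin(lat_bot))``) unless an
explicit area map is supplied; CF ``lat_bnds``/``lon_bnds``, when present in
input files, take precedence over the midpoint-bounds default (see
:mod:`lacvar.io`).

Aggregation here is *conservative averaging only*: a coarse cell value is the
area-weighted mean of the fine cells it tiles, with land-only weights on
masked fields, so that area-integrated (and land-area-weighted mean)
quantities are preserved exactly.  There is no interpolation and no support
for curvilinear grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

EARTH_RADIUS_M = 6.371e6

__all__ = [
    "EARTH_RADIUS_M",
    "GridGeometry",
    "MonthlyField",
    "RegionSeries",
    "region_mean",
    "to_global_flux",
    "aggregate_conservative",
    "coarsen_geometry",
]


def _cell_bounds(centers: np.ndarray, clamp: tuple[float, float] | None) -> np.ndarray:
    """Midpoint bounds from centers; end bounds extrapolated, optionally clamped."""
    c = np.asarray(centers, dtype=float)
    mid = 0.5 * (c[:-1] + c[1:])
    first = c[0] - (mid[0] - c[0]) if c.size > 1 else c[0] - 0.5
    last = c[-1] + (c[-1] - mid[-1]) if c.size > 1 else c[-1] + 0.5
    bounds = np.concatenate([[first], mid, [last]])
    if clamp is not None:
        bounds = np.clip(bounds, *clamp)
    return bounds


def spherical_cell_areas(lat_centers: np.ndarray, lon_centers: np.ndarray) -> np.ndarray:
    """Cell areas (m^2) on a sphere from midpoint bounds, poles clamped to +/-90."""
    lat_b = _cell_bounds(np.asarray(lat_centers, float), clamp=(-90.0, 90.0))
    lon_b = _cell_bounds(np.asarray(lon_centers, float), clamp=None)
    sin_lat = np.sin(np.deg2rad(lat_b))
    band = np.abs(np.diff(sin_lat))                    # (n_lat,)
    dlon = np.abs(np.deg2rad(np.diff(lon_b)))          # (n_lon,)
    return EARTH_RADIUS_M**2 * np.outer(band, dlon)


@dataclass(frozen=True)
class GridGeometry:
    """Regular lat/lon grid: centers, per-cell area and a land mask.

    Parameters
    ----------
    lat_centers, lon_centers
        Strictly monotone cell-center coordinates in degrees north / east.
    cell_area
        Positive per-cell area, shape ``(n_lat, n_lon)``.  If omitted,
        computed on a sphere of Earth radius from midpoint cell bounds.
    land_mask
        Boolean map of the cells that carry data (default: all True).
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    cell_area: np.ndarray = None  # type: ignore[assignment]
    land_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        if lat.ndim != 1 or lon.ndim != 1:
            raise ValueError("lat/lon centers must be 1-D")
        dlat, dlon = np.diff(lat), np.diff(lon)
        if not (np.all(dlat > 0) or np.all(dlat < 0)):
            raise ValueError("lat_centers must be strictly monotone")
        if not (np.all(dlon > 0) or np.all(dlon < 0)):
            raise ValueError("lon_centers must be strictly monotone")
        if np.any(lat < -90) or np.any(lat > 90):
            raise ValueError("lat_centers must lie within [-90, 90]")
        if lon.size > 1 and (lon.max() - lon.min()) >= 360.0:
            raise ValueError("lon_centers must span less than 360 degrees")
        area = self.cell_area
        if area is None:
            area = spherical_cell_areas(lat, lon)
        else:
            area = np.asarray(area, dtype=float)
        if area.shape != (lat.size, lon.size):
            raise ValueError("cell_area shape must be (n_lat, n_lon)")
        if np.any(area <= 0):
            raise ValueError("all cell areas must be positive")
        mask = self.land_mask
        if mask is None:
            mask = np.ones((lat.size, lon.size), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
        if mask.shape != (lat.size, lon.size):
            raise ValueError("land_mask shape must be (n_lat, n_lon)")
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        object.__setattr__(self, "cell_area", area)
        object.__setattr__(self, "land_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @property
    def land_area(self) -> float:
        """Total area (m^2) of land cells."""
        return float(self.cell_area[self.land_mask].sum())

    def same_grid(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat_centers, other.lat_centers)
            and np.allclose(self.lon_centers, other.lon_centers)
        )


@dataclass
class MonthlyField:
    """A (time, lat, lon) field of monthly values with units.

    ``years`` and ``months`` are parallel integer arrays encoding the time
    axis, which must be contiguous in calendar months and strictly
    increasing.  Values must be finite on every land cell; NaN is allowed
    off-mask only.
    """

    geometry: GridGeometry
    years: np.ndarray
    months: np.ndarray
    values: np.ndarray
    units: str
    name: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.months = np.asarray(self.months, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.months.shape or self.years.ndim != 1:
            raise ValueError("years and months must be parallel 1-D arrays")
        if not self.units:
            raise ValueError("units must be non-empty")
        n_t = self.years.size
        if self.values.shape != (n_t,) + self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(time, lat, lon) = {(n_t,) + self.geometry.shape}"
            )
        code = self.years * 12 + (self.months - 1)
        if n_t > 1 and not np.all(np.diff(code) == 1):
            raise ValueError("time axis not contiguous")
        if np.any((self.months < 1) | (self.months > 12)):
            raise ValueError("months must lie in 1..12")
        land = self.geometry.land_mask
        if not np.all(np.isfinite(self.values[:, land])):
            raise ValueError(f"non-finite values on land cells in field {self.name!r}")

    @property
    def n_time(self) -> int:
        return self.years.size

    def copy_with(self, **kw) -> "MonthlyField":
        return replace(self, **kw)


@dataclass
class RegionSeries:
    """An area-weighted regional mean time series."""

    years: np.ndarray
    months: np.ndarray | None
    values: np.ndarray
    units: str
    region: str = "global-land"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.shape != self.years.shape:
            raise ValueError("values length must equal time-axis length")


def region_mean(field: MonthlyField, mask: np.ndarray | None = None,
                region: str = "global-land") -> RegionSeries:
    """Area-weighted mean over the cells selected by ``mask`` (default: land).

    Weights are the cell areas restricted to the mask, renormalized to sum
    to one; the resulting series keeps the field's units.
    """
    geo = field.geometry
    if mask is None:
        mask = geo.land_mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != geo.shape:
        raise ValueError("mask shape does not match geometry")
    if not mask.any():
        raise ValueError("empty region")
    w = geo.cell_area[mask]
    w = w / w.sum()
    vals = field.values[:, mask] @ w
    return RegionSeries(field.years.copy(), field.months.copy(), vals,
                        units=field.units, region=region)


_FLUX_UNITS = {
    "gC m-2 yr-1": 1.0,
    "gC m-2 month-1": 12.0,
}


def to_global_flux(series: RegionSeries, total_masked_area: float) -> RegionSeries:
    """Convert an areal carbon-flux density series to a global flux in Pg C / yr.

    The series must be in ``gC m-2 yr-1`` or ``gC m-2 month-1``; the latter
    is multiplied by 12 to express a yearly rate.
    """
    if series.units not in _FLUX_UNITS:
        raise ValueError(
            f"unrecognized units {series.units!r}; accepted: {sorted(_FLUX_UNITS)}"
        )
    factor = _FLUX_UNITS[series.units] * total_masked_area * 1e-15  # g -> Pg
    return RegionSeries(series.years.copy(),
                        None if series.months is None else series.months.copy(),
                        series.values * factor, units="Pg C yr-1",
                        region=series.region)


def _normalize_factor(field_shape: tuple[int, int],
                      factor: int | tuple[int, int] | str) -> tuple[int, int]:
    n_lat, n_lon = field_shape
    if isinstance(factor, str):
        if factor != "global":
            raise ValueError(f"unknown aggregation level {factor!r}")
        return (n_lat, n_lon)
    if isinstance(factor, int):
        f_lat = f_lon = factor
    else:
        f_lat, f_lon = factor
    if f_lat < 1 or f_lon < 1:
        raise ValueError("block factors must be >= 1")
    if n_lat % f_lat or n_lon % f_lon:
        raise ValueError(
            f"block factor {(f_lat, f_lon)} does not tile grid {field_shape}"
        )
    return (f_lat, f_lon)


def coarsen_geometry(geo: GridGeometry,
                     factor: int | tuple[int, int] | str) -> GridGeometry:
    """Coarse geometry for an integer block factor.

    Coarse cell area is the summed *land* area of the block when any land
    contributes (so that land-mean aggregation is conservative), else the
    summed total area; the coarse land mask is true where any contributing
    fine cell is land.
    """
    f_lat, f_lon = _normalize_factor(geo.shape, factor)
    n_lat, n_lon = geo.shape
    area = geo.cell_area.reshape(n_lat // f_lat, f_lat, n_lon // f_lon, f_lon)
    land = geo.land_mask.reshape(n_lat // f_lat, f_lat, n_lon // f_lon, f_lon)
    land_area = (area * land).sum(axis=(1, 3))
    total_area = area.sum(axis=(1, 3))
    any_land = land.any(axis=(1, 3))
    coarse_area = np.where(any_land, land_area, total_area)
    # area-weighted mean centers of the blocks
    lat_w = geo.cell_area.sum(axis=1)
    lat_c = (
        (geo.lat_centers * lat_w).reshape(-1, f_lat).sum(axis=1)
        / lat_w.reshape(-1, f_lat).sum(axis=1)
    )
    lon_c = geo.lon_centers.reshape(-1, f_lon).mean(axis=1)
    return GridGeometry(lat_c, lon_c, cell_area=coarse_area, land_mask=any_land)


def aggregate_conservative(field: MonthlyField,
                           factor: int | tuple[int, int] | str) -> MonthlyField:
    """Coarsen by integer block factors with area-weighted (land-only) means.

    Each coarse value is the area-weighted mean of the contributing fine
    *land* cells (ocean cells carry no flux and are excluded); where a block
    has no land, all cells contribute.  The land-area-weighted global mean
    is preserved to machine precision.
    """
    geo = field.geometry
    f_lat, f_lon = _normalize_factor(geo.shape, factor)
    if (f_lat, f_lon) == (1, 1):
        return field
    n_lat, n_lon = geo.shape
    coarse_geo = coarsen_geometry(geo, (f_lat, f_lon))
    w = np.where(geo.land_mask, geo.cell_area, 0.0)
    no_land = ~coarse_geo.land_mask
    if no_land.any():
        w_all = geo.cell_area.reshape(n_lat // f_lat, f_lat, n_lon // f_lon, f_lon)
        w_blocks = np.where(
            no_land[:, None, :, None], w_all,
            w.reshape(n_lat // f_lat, f_lat, n_lon // f_lon, f_lon),
        )
    else:
        w_blocks = w.reshape(n_lat // f_lat, f_lat, n_lon // f_lon, f_lon)
    vals = np.nan_to_num(field.values, nan=0.0)
    v_blocks = vals.reshape(-1, n_lat // f_lat, f_lat, n_lon // f_lon, f_lon)
    num = (v_blocks * w_blocks[None]).sum(axis=(2, 4))
    den = w_blocks.sum(axis=(1, 3))
    coarse_vals = num / den[None]
    return MonthlyField(coarse_geo, field.years.copy(), field.months.copy(),
                        coarse_vals, units=field.units, name=field.name)
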