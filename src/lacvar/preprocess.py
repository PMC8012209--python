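"""Derivation of VPD and interannual-variability anomalies.

The interannual variability (IAV) of a monthly field is what remains after
removing, separately for every grid cell and every calendar month, an
ordinary-least-squares line in the year index.  Fitting the line removes the
per-month mean (the seasonal cycle) and the per-month long-term linear trend
jointly, so the resulting anomalies have *exactly* zero mean and zero trend
for each calendar month — a linear projection, hence idempotent, and exactly
invertible given the stored climatology.

VPD is computed from air temperature and relative humidity with the Magnus
(FAO-56) saturation vapour pressure over water.  When daily inputs exist,
VPD is computed at daily resolution first and only then averaged to monthly
means; a monthly-input fallback exists but is flagged, because e_sat is
convex in temperature and the order of averaging matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridGeometry, MonthlyField

__all__ = [
    "AnomalyField",
    "Climatology",
    "saturation_vapour_pressure",
    "vpd_from_t_rh",
    "average_to_monthly",
    "compute_anomalies",
    "annual_means",
]


@dataclass
class AnomalyField(MonthlyField):
    """A MonthlyField whose per-cell, per-calendar-month mean and linear
    trend in year are both zero (to 1e-10)."""

    source_name: str = ""
    climatology_period: tuple[int, int] | None = None


@dataclass
class Climatology:
    """Removed per-calendar-month OLS line: intercept + slope * (year - year0).

    ``mean`` and ``slope`` have shape (12, n_lat, n_lon); ``year0`` is the
    mean year of the fit window per calendar month, so ``mean`` is the
    climatological monthly mean over that window.
    """

    mean: np.ndarray
    slope: np.ndarray
    year0: np.ndarray  # (12,)
    units: str
    source_name: str = ""

    def evaluate(self, years: np.ndarray, months: np.ndarray) -> np.ndarray:
        """Reconstruct the removed seasonal-cycle + trend term per time step."""
        m = np.asarray(months, int) - 1
        y = np.asarray(years, float)
        return self.mean[m] + self.slope[m] * (y - self.year0[m])[:, None, None]


def saturation_vapour_pressure(t_air):
    """Magnus saturation vapour pressure over water, in kPa, for T in deg C.

    e_sat(T) = 0.6108 * exp(17.27 T / (T + 237.3))
    """
    t = np.asarray(t_air, dtype=float)
    if np.any(t <= -80.0) or np.any(t >= 60.0):
        raise ValueError("air temperature outside plausible range (-80, 60) degC")
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def vpd_from_t_rh(t_air, rh):
    """Vapour pressure deficit (kPa) from temperature (degC) and RH (%).

    VPD = e_sat(T) * (1 - RH/100), elementwise at the input resolution
    (daily preferred; see module docstring).
    """
    t = np.asarray(t_air, dtype=float)
    r = np.asarray(rh, dtype=float)
    if np.any(r < -1e-6) or np.any(r > 100.0 + 1e-6):
        raise ValueError("relative humidity outside [0, 100] %")
    r = np.clip(r, 0.0, 100.0)
    return saturation_vapour_pressure(t) * (1.0 - r / 100.0)


def average_to_monthly(daily_values: np.ndarray, years: np.ndarray,
                       months: np.ndarray, geometry: GridGeometry,
                       units: str, name: str = "",
                       max_missing_fraction: float = 0.0) -> MonthlyField:
    """Average a daily (time, lat, lon) array to a MonthlyField.

    ``years``/``months`` give the calendar month of every daily step.  A
    month whose NaN fraction exceeds ``max_missing_fraction`` on land is an
    error naming the month.
    """
    daily_values = np.asarray(daily_values, dtype=float)
    years = np.asarray(years, int)
    months = np.asarray(months, int)
    code = years * 12 + (months - 1)
    uniq, inverse = np.unique(code, return_inverse=True)
    out = np.empty((uniq.size,) + geometry.shape)
    land = geometry.land_mask
    for i, c in enumerate(uniq):
        sel = inverse == i
        block = daily_values[sel]
        missing = np.mean(~np.isfinite(block[:, land])) if land.any() else 0.0
        if missing > max_missing_fraction:
            y, m = divmod(int(c), 12)
            raise ValueError(f"month {y:04d}-{m + 1:02d} has missing fraction "
                             f"{missing:.3f} > {max_missing_fraction}")
        out[i] = np.nanmean(block, axis=0)
    return MonthlyField(geometry, uniq // 12, uniq % 12 + 1, out,
                        units=units, name=name)


def compute_anomalies(field: MonthlyField,
                      period: tuple[int, int] | None = None,
                      min_years: int = 10) -> tuple[AnomalyField, Climatology]:
    """Remove the per-cell, per-calendar-month OLS line in year index.

    Parameters
    ----------
    field
        Input monthly field.
    period
        Inclusive (first_year, last_year) window over which the line is fit;
        default is the full span of the field.  The line is subtracted from
        *all* time steps, but its coefficients come from the window.
    min_years
        Minimum number of years required per calendar month in the window.
    """
    years, months = field.years, field.months
    if period is None:
        fit_sel = np.ones(field.n_time, dtype=bool)
    else:
        fit_sel = (years >= period[0]) & (years <= period[1])
    mean = np.zeros((12,) + field.geometry.shape)
    slope = np.zeros_like(mean)
    year0 = np.zeros(12)
    anoms = field.values.copy()
    for m in range(1, 13):
        in_month = months == m
        fit_m = in_month & fit_sel
        n = int(fit_m.sum())
        if n < min_years:
            raise ValueError(
                f"calendar month {m} has {n} years in fit window; need >= {min_years}"
            )
        y_fit = years[fit_m].astype(float)
        ybar = y_fit.mean()
        x = y_fit - ybar
        v = field.values[fit_m]  # (n, lat, lon)
        mu = v.mean(axis=0)
        sxx = float((x**2).sum())
        b = np.tensordot(x, v - mu, axes=(0, 0)) / sxx if sxx > 0 else np.zeros_like(mu)
        mean[m - 1], slope[m - 1], year0[m - 1] = mu, b, ybar
        x_all = years[in_month].astype(float) - ybar
        anoms[in_month] -= mu[None] + x_all[:, None, None] * b[None]
    clim = Climatology(mean, slope, year0, units=field.units,
                       source_name=field.name)
    anom = AnomalyField(field.geometry, years.copy(), months.copy(), anoms,
                        units=field.units, name=field.name,
                        source_name=field.name,
                        climatology_period=(int(years.min()), int(years.max()))
                        if period is None else period)
    return anom, clim


def annual_means(anom: MonthlyField) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean over the 12 months of each complete calendar year.

    Returns ``(years, values)`` with values of shape (n_year, lat, lon);
    partial years are dropped (an error if none is complete).
    """
    uniq_years = np.unique(anom.years)
    keep, out = [], []
    for y in uniq_years:
        sel = anom.years == y
        if int(sel.sum()) == 12:
            keep.append(y)
            out.append(anom.values[sel].mean(axis=0))
    if not keep:
        raise ValueError("no complete calendar year in field")
    return np.asarray(keep, int), np.asarray(out)
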