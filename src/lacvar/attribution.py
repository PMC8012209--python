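"""Month-wise regression attribution of NBP anomalies to meteorological drivers.

For every grid cell s and calendar month m, NBP anomalies over the N years
are regressed (ordinary least squares, no intercept — anomalies are exactly
zero-mean per month by construction) on a named set of driver anomalies,
by default {SM, T, VPD, R}:

    NBP*_{s,m} = beta^SM SM + beta^T T + beta^VPD VPD + beta^R R

The fitted betas reconstruct per-driver NBP components whose sum plus an
orthogonal residual equals the input NBP exactly.  Alternative driver sets
(dropping VPD, replacing it by relative humidity, or a T x SM interaction
built as the elementwise anomaly product) go through the same named-driver
interface.  Temperature and VPD are left collinear on purpose — their
attribution is only reported jointly downstream — and degenerate designs
(zero-variance drivers in deserts/ice, near-singular months) fall back to a
flagged minimum-norm solution.

Factorial differences between experiments are summarized per cell as
delta-sigma = sigma(ExpA) - sigma(CTL), by default on annual means with
N-1 normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import MonthlyField
from .preprocess import AnomalyField, annual_means

__all__ = [
    "SensitivityMaps",
    "ComponentSet",
    "fit_monthwise_ols",
    "reconstruct_components",
    "delta_sigma",
    "regression_r2",
]

COND_THRESHOLD = 1e8


@dataclass
class SensitivityMaps:
    """Per-cell, per-calendar-month regression coefficients.

    ``beta`` has shape (n_lat, n_lon, 12, n_driver), ordered as
    ``driver_names``; ``dropped`` flags drivers excluded for zero variance
    (their beta is 0) and ``near_singular`` flags (s, m) designs solved by
    minimum-norm least squares.
    """

    beta: np.ndarray
    driver_names: tuple[str, ...]
    experiment: str = ""
    dropped: np.ndarray = None  # type: ignore[assignment]
    near_singular: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dropped is None:
            self.dropped = np.zeros(self.beta.shape, dtype=bool)
        if self.near_singular is None:
            self.near_singular = np.zeros(self.beta.shape[:3], dtype=bool)

    def month_mean(self) -> np.ndarray:
        """Mean beta over calendar months, shape (lat, lon, n_driver) —
        the natural per-cell estimate of a month-invariant sensitivity."""
        return self.beta.mean(axis=2)


@dataclass
class ComponentSet:
    """Driver-attributed NBP component series plus residual."""

    components: dict[str, AnomalyField]
    residual: AnomalyField | None
    experiment: str = ""

    @property
    def total(self) -> np.ndarray:
        """NBP*, the regression-explained part."""
        return sum(f.values for f in self.components.values())

    def t_vpd(self) -> np.ndarray:
        """Joint T&VPD component series (reported jointly because T and VPD
        are partially collinear)."""
        return self.components["T"].values + self.components["VPD"].values


def _check_aligned(nbp: MonthlyField, drivers: dict[str, MonthlyField]) -> None:
    for name, d in drivers.items():
        if not d.geometry.same_grid(nbp.geometry):
            raise ValueError(f"driver {name!r} geometry mismatch")
        if not (np.array_equal(d.years, nbp.years)
                and np.array_equal(d.months, nbp.months)):
            raise ValueError(f"driver {name!r} calendar mismatch")


def fit_monthwise_ols(nbp: AnomalyField, drivers: dict[str, AnomalyField],
                      min_years: int = 10, experiment: str = ""
                      ) -> SensitivityMaps:
    """Fit the month-wise no-intercept OLS at every cell.

    Zero-variance drivers are dropped (beta = 0, flagged).  Designs with
    condition number above 1e8 are solved by minimum-norm least squares and
    flagged.  Only land cells are fitted; betas elsewhere are 0.
    """
    _check_aligned(nbp, drivers)
    names = tuple(drivers)
    n_lat, n_lon = nbp.geometry.shape
    n_d = len(names)
    beta = np.zeros((n_lat, n_lon, 12, n_d))
    dropped = np.zeros_like(beta, dtype=bool)
    near_singular = np.zeros((n_lat, n_lon, 12), dtype=bool)
    land = nbp.geometry.land_mask
    flat_land = np.flatnonzero(land.ravel())

    for m in range(1, 13):
        sel = nbp.months == m
        n = int(sel.sum())
        if n < min_years:
            raise ValueError(f"month {m}: {n} years < minimum {min_years}")
        # X: (cells, N, d); y: (cells, N)
        X = np.stack(
            [drivers[k].values[sel].reshape(n, -1)[:, flat_land].T for k in names],
            axis=2,
        )
        y = nbp.values[sel].reshape(n, -1)[:, flat_land].T
        keep = X.std(axis=1) > 0.0          # (cells, d): non-constant drivers
        Xk = np.where(keep[:, None, :], X, 0.0)
        U, S, Vt = np.linalg.svd(Xk, full_matrices=False)
        smax = S[:, :1]
        tol_sing = smax * max(n, n_d) * np.finfo(float).eps
        # condition number over the retained (non-dropped) column space only
        n_kept = keep.sum(axis=1)
        s_min = np.take_along_axis(S, np.maximum(n_kept - 1, 0)[:, None],
                                   axis=1)[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(s_min > 0, smax[:, 0] / s_min, np.inf)
        flag = (cond > COND_THRESHOLD) & (n_kept > 0)
        Sinv = np.where(S > tol_sing, 1.0 / np.where(S > 0, S, 1.0), 0.0)
        b = np.einsum("cdk,ck,cnk,cn->cd", np.swapaxes(Vt, 1, 2), Sinv, U, y)
        b = np.where(keep, b, 0.0)
        bm = np.zeros((n_lat * n_lon, n_d))
        bm[flat_land] = b
        beta[:, :, m - 1, :] = bm.reshape(n_lat, n_lon, n_d)
        dm = np.zeros((n_lat * n_lon, n_d), dtype=bool)
        dm[flat_land] = ~keep
        dropped[:, :, m - 1, :] = dm.reshape(n_lat, n_lon, n_d)
        fm = np.zeros(n_lat * n_lon, dtype=bool)
        fm[flat_land] = flag
        near_singular[:, :, m - 1] = fm.reshape(n_lat, n_lon)

    return SensitivityMaps(beta, names, experiment=experiment,
                           dropped=dropped, near_singular=near_singular)


def reconstruct_components(beta: SensitivityMaps,
                           drivers: dict[str, AnomalyField],
                           nbp: AnomalyField | None = None,
                           experiment: str = "") -> ComponentSet:
    """Per-driver component series component_d(s, t) = beta[s, m(t), d] * driver_d(s, t).

    When ``nbp`` is supplied the residual NBP - sum(components) is included.
    The betas may come from a different experiment than the drivers (the
    cross-experiment application needed by the LAC partition).
    """
    if tuple(drivers) != beta.driver_names:
        raise ValueError(
            f"driver set {tuple(drivers)} does not match fitted set "
            f"{beta.driver_names}"
        )
    any_d = next(iter(drivers.values()))
    m_idx = any_d.months - 1
    comps: dict[str, AnomalyField] = {}
    for j, name in enumerate(beta.driver_names):
        d = drivers[name]
        b_t = np.moveaxis(beta.beta[:, :, m_idx, j], 2, 0)  # (t, lat, lon)
        comps[name] = AnomalyField(d.geometry, d.years.copy(), d.months.copy(),
                                   b_t * d.values, units="NBP units",
                                   name=f"NBP^{name}", source_name=name)
    residual = None
    if nbp is not None:
        res = nbp.values - sum(c.values for c in comps.values())
        residual = AnomalyField(nbp.geometry, nbp.years.copy(),
                                nbp.months.copy(), res, units=nbp.units,
                                name="residual", source_name=nbp.name)
    return ComponentSet(comps, residual, experiment=experiment)


def _sigma(field: MonthlyField, annualize: bool) -> np.ndarray:
    if annualize:
        _, ann = annual_means(field)
        return ann.std(axis=0, ddof=1)
    return field.values.std(axis=0, ddof=1)


def delta_sigma(ctl: MonthlyField, expa: MonthlyField,
                annualize: bool = True) -> np.ndarray:
    """Per-cell sigma(ExpA) - sigma(CTL); negative = variability suppressed.

    Standard deviations are of annual means by default (monthly anomalies
    when ``annualize`` is False), with N-1 normalization.
    """
    if not ctl.geometry.same_grid(expa.geometry):
        raise ValueError("CTL/ExpA geometry mismatch")
    if not np.array_equal(ctl.years, expa.years):
        raise ValueError("CTL/ExpA calendar mismatch")
    return _sigma(expa, annualize) - _sigma(ctl, annualize)


def regression_r2(components: ComponentSet, nbp: AnomalyField
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Explained-variance fraction 1 - var(residual)/var(NBP) per cell.

    Pooled over all months.  Returns ``(r2, low_variance_flag)``; cells with
    (near-)zero NBP variance get NaN and the flag.
    """
    if components.residual is None:
        raise ValueError("ComponentSet has no residual; fit with nbp supplied")
    var_nbp = nbp.values.var(axis=0, ddof=1)
    var_res = components.residual.values.var(axis=0, ddof=1)
    tiny = np.finfo(float).tiny
    flag = var_nbp <= np.finfo(float).eps * np.nanmax(var_nbp, initial=tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - var_res / var_nbp
    r2 = np.where(flag, np.nan, r2)
    return r2, flag
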