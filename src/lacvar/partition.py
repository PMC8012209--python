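"""Variance partitioning downstream of the regression components.

Implements the LAC/non-LAC split of the joint T&VPD contribution, the
scale-dependent contribution profile, variance budgets with covariances,
the driver-variance vs sensitivity decomposition of factorial variance
change, the GPP/ReD variance budget, hotspot classification, and
multi-replicate spread bounds.

LAC split
---------
The experiment-A meteorology is, by construction, the temperature and VPD
that would occur under climatologically normal soil moisture.  The
non-coupled part of the control T&VPD component is therefore reconstructed
by applying the *control* sensitivities to the ExpA drivers:

    nonLAC(s, t) = beta_CTL^T(s, m) T_ExpA(s, t) + beta_CTL^VPD(s, m) VPD_ExpA(s, t)

and the coupling-mediated variance is the per-cell remainder

    sigma2_LAC = sigma2(T&VPD, CTL) - sigma2(nonLAC),   floored at 0,

with floored cells counted and flagged.  Using CTL betas on both sides
isolates the change in meteorology from any change in sensitivity; the
alternative (ExpA betas) is available via ``beta_expa`` for sensitivity
checks.

Scale ladder
------------
Component *series* are aggregated conservatively to each level first; the
per-coarse-cell annual variances are then spatially averaged (area-weighted
over land) and normalized so the four contributions {SM, LAC T&VPD,
nonLAC T&VPD, R} sum to one at every level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attribution import ComponentSet, SensitivityMaps
from .grid import GridGeometry, MonthlyField, aggregate_conservative, region_mean
from .preprocess import AnomalyField, annual_means

__all__ = [
    "LacSplit",
    "ContributionProfile",
    "VarianceBudget",
    "SpreadBounds",
    "partition_t_vpd_lac",
    "contribution_profile",
    "variance_budget",
    "decompose_variance_change",
    "gpp_red_budget",
    "hotspot_classes",
    "spread_bounds",
    "HOTSPOT_CLASSES",
]

CONTRIBUTIONS = ("SM", "LAC", "nonLAC", "R")


@dataclass
class LacSplit:
    """Per-cell split of the control T&VPD variance into LAC and non-LAC."""

    sigma2_t_vpd_ctl: np.ndarray
    sigma2_nonlac: np.ndarray
    sigma2_lac: np.ndarray
    floored: np.ndarray           # cells where the remainder was clipped at 0
    nonlac_series: np.ndarray | None = None
    method: str = "ctl-betas-on-expa-drivers"

    @property
    def n_floored(self) -> int:
        return int(self.floored.sum())


@dataclass
class ContributionProfile:
    """Variance fractions of the four contributions per aggregation level."""

    levels: list
    fractions: dict[str, np.ndarray]  # name -> (n_level,)
    weighting: str = "area-weighted-land"

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.fractions,
                            index=[str(lv) for lv in self.levels])


@dataclass
class VarianceBudget:
    """Variances + pairwise covariances of component series (N-1 normalized)."""

    names: tuple[str, ...]
    variances: dict[str, float]
    covariances: dict[tuple[str, str], float]
    total: float
    experiment: str = ""

    def check_identity(self, rtol: float = 1e-10) -> bool:
        s = sum(self.variances.values()) + 2 * sum(self.covariances.values())
        return abs(s - self.total) <= rtol * max(abs(self.total), 1e-300)


@dataclass
class SpreadBounds:
    """Across-replicate mean and outer/inner spread per level and component."""

    levels: list
    mean: dict[str, np.ndarray]
    outer: dict[str, np.ndarray]
    inner: dict[str, np.ndarray]


def _annual_var(values: np.ndarray, template: MonthlyField,
                annualize: bool) -> np.ndarray:
    f = MonthlyField(template.geometry, template.years, template.months,
                     values, units="1")
    if annualize:
        _, ann = annual_means(f)
        return ann.var(axis=0, ddof=1)
    return values.var(axis=0, ddof=1)


def _nonlac_values(beta: SensitivityMaps, drivers_expa: dict[str, AnomalyField]
                   ) -> np.ndarray:
    for k in ("T", "VPD"):
        if k not in drivers_expa:
            raise ValueError(f"missing driver {k!r} in ExpA driver set")
        if k not in beta.driver_names:
            raise ValueError(f"driver {k!r} absent from fitted driver set")
    t, v = drivers_expa["T"], drivers_expa["VPD"]
    m_idx = t.months - 1
    jt = beta.driver_names.index("T")
    jv = beta.driver_names.index("VPD")
    bt = np.moveaxis(beta.beta[:, :, m_idx, jt], 2, 0)
    bv = np.moveaxis(beta.beta[:, :, m_idx, jv], 2, 0)
    return bt * t.values + bv * v.values


def partition_t_vpd_lac(beta_ctl: SensitivityMaps,
                        components_ctl: ComponentSet,
                        drivers_expa: dict[str, AnomalyField],
                        annualize: bool = True,
                        beta_expa: SensitivityMaps | None = None) -> LacSplit:
    """Split the control T&VPD component variance into LAC and non-LAC parts.

    ``beta_expa``, when given, switches to the alternative method (ExpA
    sensitivities applied to ExpA meteorology) for sensitivity analysis.
    """
    t_field = components_ctl.components["T"]
    tv_ctl = components_ctl.t_vpd()
    beta_used = beta_ctl if beta_expa is None else beta_expa
    nonlac = _nonlac_values(beta_used, drivers_expa)
    s2_tv = _annual_var(tv_ctl, t_field, annualize)
    s2_non = _annual_var(nonlac, drivers_expa["T"], annualize)
    raw = s2_tv - s2_non
    floored = raw < 0
    s2_lac = np.where(floored, 0.0, raw)
    method = ("ctl-betas-on-expa-drivers" if beta_expa is None
              else "expa-betas-on-expa-drivers")
    return LacSplit(s2_tv, np.where(floored, s2_tv, s2_non), s2_lac, floored,
                    nonlac_series=nonlac, method=method)


def _land_mean(var_map: np.ndarray, geo: GridGeometry,
               area_weighted: bool) -> float:
    land = geo.land_mask
    if area_weighted:
        w = geo.cell_area[land]
        return float((var_map[land] * w).sum() / w.sum())
    return float(var_map[land].mean())


def contribution_profile(components_ctl: ComponentSet,
                         lac: LacSplit,
                         geometry: GridGeometry,
                         levels: list,
                         annualize: bool = True,
                         area_weighted: bool = True) -> ContributionProfile:
    """Variance fractions of {SM, LAC, nonLAC, R} at each aggregation level.

    At every level the component time series (and the non-LAC series from
    the LAC split) are conservatively aggregated, per-coarse-cell variances
    computed, the aggregated T&VPD variance re-split by the same remainder
    rule, and the spatial average of variances normalized to fractions.
    """
    if lac.nonlac_series is None:
        raise ValueError("LacSplit must carry the non-LAC series")
    sm = components_ctl.components["SM"]
    template = sm
    series = {
        "SM": sm.values,
        "TV": components_ctl.t_vpd(),
        "nonLAC": lac.nonlac_series,
        "R": components_ctl.components["R"].values,
    }
    fracs = {k: np.empty(len(levels)) for k in CONTRIBUTIONS}
    for i, lv in enumerate(levels):
        agg = {}
        for k, v in series.items():
            f = MonthlyField(geometry, template.years, template.months, v,
                             units="1")
            agg[k] = aggregate_conservative(f, lv)
        geo_c = agg["SM"].geometry
        var = {k: _annual_var(a.values, a, annualize) for k, a in agg.items()}
        lac_var = np.clip(var["TV"] - var["nonLAC"], 0.0, None)
        nonlac_var = np.where(var["TV"] - var["nonLAC"] < 0, var["TV"],
                              var["nonLAC"])
        means = {
            "SM": _land_mean(var["SM"], geo_c, area_weighted),
            "LAC": _land_mean(lac_var, geo_c, area_weighted),
            "nonLAC": _land_mean(nonlac_var, geo_c, area_weighted),
            "R": _land_mean(var["R"], geo_c, area_weighted),
        }
        total = sum(means.values())
        for k in CONTRIBUTIONS:
            fracs[k][i] = means[k] / total
    return ContributionProfile(list(levels), fracs,
                               weighting="area-weighted-land" if area_weighted
                               else "unweighted-land")


def variance_budget(components: ComponentSet, geometry: GridGeometry,
                    scope: str = "global-mean",
                    annualize: bool = True) -> VarianceBudget:
    """Variances and pairwise covariances of the component series.

    ``scope='global-mean'`` (default) works on area-weighted global-land
    mean series; the budget identity Var(sum) = sum Var + 2 sum Cov holds
    to machine precision.
    """
    names = tuple(components.components)
    series = []
    for k in names:
        f = components.components[k]
        if scope == "global-mean":
            s = region_mean(f).values
            if annualize:
                g = MonthlyField(
                    GridGeometry(np.array([0.0]), np.array([0.0]),
                                 cell_area=np.array([[1.0]])),
                    f.years, f.months, s[:, None, None], units="1")
                _, ann = annual_means(g)
                s = ann[:, 0, 0]
        else:
            raise ValueError(f"unknown scope {scope!r}")
        series.append(s)
    arr = np.asarray(series)
    cov = np.cov(arr, ddof=1)
    variances = {k: float(cov[i, i]) for i, k in enumerate(names)}
    covariances = {(names[i], names[j]): float(cov[i, j])
                   for i in range(len(names)) for j in range(i + 1, len(names))}
    total = float(arr.sum(axis=0).var(ddof=1))
    return VarianceBudget(names, variances, covariances, total,
                          experiment=components.experiment)


def decompose_variance_change(beta_ctl: SensitivityMaps,
                              beta_expa: SensitivityMaps,
                              drivers_ctl: dict[str, AnomalyField],
                              drivers_expa: dict[str, AnomalyField],
                              annualize: bool = True
                              ) -> dict[str, dict[str, np.ndarray]]:
    """Split each component's variance change into driver-variance and
    sensitivity effects.

    For each driver d, per cell:

        driver effect      = var(b_ctl d_expa) - var(b_ctl d_ctl)
        sensitivity effect = var(b_expa d_expa) - var(b_ctl d_expa)

    The two telescope exactly to the total per-component variance change
    var(b_expa d_expa) - var(b_ctl d_ctl).
    """
    if beta_ctl.driver_names != beta_expa.driver_names:
        raise ValueError("driver-set mismatch between experiments")
    if tuple(drivers_ctl) != beta_ctl.driver_names \
            or tuple(drivers_expa) != beta_ctl.driver_names:
        raise ValueError("driver dict does not match fitted driver set")
    out: dict[str, dict[str, np.ndarray]] = {}
    for j, name in enumerate(beta_ctl.driver_names):
        dc, dx = drivers_ctl[name], drivers_expa[name]
        m_idx = dc.months - 1
        b_c = np.moveaxis(beta_ctl.beta[:, :, m_idx, j], 2, 0)
        b_x = np.moveaxis(beta_expa.beta[:, :, m_idx, j], 2, 0)
        v_cc = _annual_var(b_c * dc.values, dc, annualize)
        v_cx = _annual_var(b_c * dx.values, dx, annualize)
        v_xx = _annual_var(b_x * dx.values, dx, annualize)
        out[name] = {
            "driver_variance_effect": v_cx - v_cc,
            "sensitivity_effect": v_xx - v_cx,
            "total_change": v_xx - v_cc,
        }
    return out


def gpp_red_budget(gpp_ctl: np.ndarray, red_ctl: np.ndarray,
                   gpp_expa: np.ndarray, red_expa: np.ndarray
                   ) -> dict[str, float]:
    """Drivers of the change in NBP variance: Delta Var(NBP) =
    Delta Var(GPP) + Delta Var(ReD) - 2 Delta Cov(GPP, ReD), each
    Delta = ExpA - CTL, on the supplied (global-mean anomaly) series."""
    g_c, r_c = np.asarray(gpp_ctl, float), np.asarray(red_ctl, float)
    g_x, r_x = np.asarray(gpp_expa, float), np.asarray(red_expa, float)
    if not (g_c.shape == r_c.shape and g_x.shape == r_x.shape):
        raise ValueError("series length mismatch")

    def var(a):
        return float(np.var(a, ddof=1))

    def cov(a, b):
        return float(np.cov(a, b, ddof=1)[0, 1])

    d_gpp = var(g_x) - var(g_c)
    d_red = var(r_x) - var(r_c)
    d_cov = cov(g_x, r_x) - cov(g_c, r_c)
    return {
        "dvar_gpp": d_gpp,
        "dvar_red": d_red,
        "minus_2dcov": -2.0 * d_cov,
        "dvar_nbp": d_gpp + d_red - 2.0 * d_cov,
    }


HOTSPOT_CLASSES = {0: "weak-LAC", 1: "T-only", 2: "VPD-only", 3: "strong-LAC"}


def hotspot_classes(sigma_nbp_ctl: np.ndarray, dsig_t: np.ndarray,
                    dsig_vpd: np.ndarray, thresholds: tuple[float, float],
                    land_mask: np.ndarray | None = None) -> np.ndarray:
    """Classify land cells by coupling strength.

    A cell is a T (VPD) hotspot when its delta-sigma lies *strictly below*
    the negative threshold (ties are not hotspots); both -> strong-LAC,
    neither -> weak-LAC.  Thresholds must be supplied explicitly (defaults
    live in pipeline configuration, never here).  Returns an integer map
    per HOTSPOT_CLASSES; -1 off land.
    """
    if thresholds is None or len(thresholds) != 2:
        raise ValueError("thresholds (t_threshold, vpd_threshold) required")
    th_t, th_v = thresholds
    t_hot = dsig_t < -abs(th_t)
    v_hot = dsig_vpd < -abs(th_v)
    cls = np.where(t_hot & v_hot, 3, np.where(t_hot, 1, np.where(v_hot, 2, 0)))
    if land_mask is not None:
        cls = np.where(land_mask, cls, -1)
    return cls


def spread_bounds(profiles: list[ContributionProfile]) -> SpreadBounds:
    """Across-replicate spread of contribution profiles.

    Outer bound: standard deviation across replicates per level.  Inner
    bound: the same after removing each replicate's mean contribution across
    all levels (spread in the *tendency* only).  N-1 normalization.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 replicates")
    levels = profiles[0].levels
    for p in profiles[1:]:
        if [str(lv) for lv in p.levels] != [str(lv) for lv in levels]:
            raise ValueError("replicates have mismatched aggregation ladders")
    mean, outer, inner = {}, {}, {}
    for k in CONTRIBUTIONS:
        arr = np.stack([p.fractions[k] for p in profiles])  # (rep, level)
        mean[k] = arr.mean(axis=0)
        outer[k] = arr.std(axis=0, ddof=1)
        demeaned = arr - arr.mean(axis=1, keepdims=True)
        inner[k] = demeaned.std(axis=0, ddof=1)
    return SpreadBounds(list(levels), mean, outer, inner)
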