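"""LAC/non-LAC split, contribution profiles, variance budgets, hotspot
classes and spread bounds."""

import numpy as np
import pytest

from conftest import make_field
from lacvar.attribution import fit_monthwise_ols, reconstruct_components
from lacvar.partition import (
    contribution_profile,
    decompose_variance_change,
    gpp_red_budget,
    hotspot_classes,
    partition_t_vpd_lac,
    spread_bounds,
    variance_budget,
    ContributionProfile,
)
from lacvar.preprocess import AnomalyField


def _anom(values, **kw):
    f = make_field(values, **kw)
    return AnomalyField(f.geometry, f.years, f.months, f.values,
                        units=f.units, name=f.name)


def _tiny_fit(rng, n_years=10, n_lat=2, n_lon=2):
    shape = (12 * n_years, n_lat, n_lon)
    drivers = {k: _anom(rng.normal(size=shape)) for k in ("SM", "T", "VPD", "R")}
    nbp = _anom(rng.normal(size=shape))
    beta = fit_monthwise_ols(nbp, drivers)
    comps = reconstruct_components(beta, drivers, nbp=nbp)
    return nbp, drivers, beta, comps


class TestLacSplit:
    def test_identical_meteorology_gives_zero_lac(self):
        rng = np.random.default_rng(0)
        nbp, drivers, beta, comps = _tiny_fit(rng)
        lac = partition_t_vpd_lac(beta, comps, drivers)
        assert np.max(np.abs(lac.sigma2_lac)) < 1e-12
        # additivity holds exactly even with flooring
        np.testing.assert_allclose(lac.sigma2_lac + lac.sigma2_nonlac,
                                   lac.sigma2_t_vpd_ctl, atol=1e-12)

    def test_zero_expa_meteorology_gives_full_lac(self):
        rng = np.random.default_rng(1)
        nbp, drivers, beta, comps = _tiny_fit(rng)
        d_expa = dict(drivers)
        d_expa["T"] = _anom(np.zeros_like(drivers["T"].values))
        d_expa["VPD"] = _anom(np.zeros_like(drivers["VPD"].values))
        lac = partition_t_vpd_lac(beta, comps, d_expa)
        np.testing.assert_allclose(lac.sigma2_nonlac, 0.0, atol=1e-12)
        np.testing.assert_allclose(lac.sigma2_lac, lac.sigma2_t_vpd_ctl,
                                   atol=1e-12)

    def test_flooring_is_flagged(self):
        rng = np.random.default_rng(2)
        nbp, drivers, beta, comps = _tiny_fit(rng)
        # inflate ExpA meteorology so nonLAC variance exceeds the CTL T&VPD
        d_expa = dict(drivers)
        d_expa["T"] = _anom(3.0 * drivers["T"].values)
        d_expa["VPD"] = _anom(3.0 * drivers["VPD"].values)
        lac = partition_t_vpd_lac(beta, comps, d_expa)
        assert lac.n_floored > 0
        assert np.all(lac.sigma2_lac >= 0.0)
        np.testing.assert_allclose(lac.sigma2_lac + lac.sigma2_nonlac,
                                   lac.sigma2_t_vpd_ctl, atol=1e-12)

    def test_missing_vpd_errors(self):
        rng = np.random.default_rng(3)
        nbp, drivers, beta, comps = _tiny_fit(rng)
        bad = {k: v for k, v in drivers.items() if k != "VPD"}
        with pytest.raises(ValueError, match="VPD"):
            partition_t_vpd_lac(beta, comps, bad)


class TestContributionProfile:
    def test_radiation_only_component(self):
        rng = np.random.default_rng(4)
        nbp, drivers, beta, comps = _tiny_fit(rng, n_lat=2, n_lon=4)
        for name in ("SM", "T", "VPD"):
            comps.components[name].values[:] = 0.0
        beta.beta[..., :3] = 0.0
        d_expa = {k: _anom(np.zeros_like(v.values))
                  for k, v in drivers.items()}
        lac = partition_t_vpd_lac(beta, comps, d_expa)
        prof = contribution_profile(comps, lac, nbp.geometry, [1, 2, "global"])
        np.testing.assert_allclose(prof.fractions["R"], 1.0, atol=1e-10)

    def test_fractions_sum_to_one_at_every_level(self, fitted_system):
        from lacvar.pipeline import default_levels

        comps = fitted_system["comps_ctl"]
        lac = partition_t_vpd_lac(fitted_system["beta_ctl"], comps,
                                  fitted_system["drivers_expa"])
        geo = fitted_system["pair"].geometry
        prof = contribution_profile(comps, lac, geo, default_levels(*geo.shape))
        total = sum(np.asarray(prof.fractions[k]) for k in prof.fractions)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)
        for k in prof.fractions:
            assert np.all(np.asarray(prof.fractions[k]) >= 0.0)

    def test_lac_fraction_grows_with_aggregation_for_coherent_sm(self):
        """When soil moisture rides on the coherent large-scale modes and
        T/VPD carry strong local noise, the coupling-mediated contribution
        decays more slowly under aggregation than the non-coupled one."""
        from lacvar import PipelineConfig, coherent_sm_config, run_pipeline

        rises = 0
        for seed in range(10):
            res = run_pipeline(PipelineConfig(
                generator=coherent_sm_config(seed=seed),
                out_dir="/tmp/lacvar_test_coh", seed=seed))
            f = res.profile.fractions["LAC"]
            rises += f[-1] > f[0]
        assert rises == 10

    def test_bad_level_errors(self):
        rng = np.random.default_rng(5)
        nbp, drivers, beta, comps = _tiny_fit(rng)
        lac = partition_t_vpd_lac(beta, comps, drivers)
        with pytest.raises(ValueError, match="tile"):
            contribution_profile(comps, lac, nbp.geometry, [3])


class TestVarianceBudget:
    def test_identity_on_fitted_components(self, fitted_system):
        budget = variance_budget(fitted_system["comps_ctl"],
                                 fitted_system["pair"].geometry)
        assert budget.check_identity(rtol=1e-10)

    def test_identical_components_double_variance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12 * 10, 1, 1))
        nbp, drivers, beta, comps = _tiny_fit(rng, n_lat=1, n_lon=1)
        for name in comps.components:
            comps.components[name].values[:] = 0.0
        comps.components["T"].values[:] = x
        comps.components["VPD"].values[:] = x
        budget = variance_budget(comps, nbp.geometry, annualize=False)
        var_x = x[:, 0, 0].var(ddof=1)
        assert budget.total == pytest.approx(4.0 * var_x, rel=1e-10)

    def test_independent_components_have_small_covariance(self):
        """Components built from independent noise: each pairwise covariance
        is within 3 sampling standard deviations of zero."""
        rng = np.random.default_rng(7)
        n_years = 40
        nbp, drivers, beta, comps = _tiny_fit(rng, n_years=n_years,
                                              n_lat=1, n_lon=1)
        for name in comps.components:
            comps.components[name].values[:] = rng.normal(
                size=comps.components[name].values.shape)
        budget = variance_budget(comps, nbp.geometry, annualize=True)
        n = n_years
        for (a, b), c in budget.covariances.items():
            sd_a = np.sqrt(budget.variances[a])
            sd_b = np.sqrt(budget.variances[b])
            # sampling sd of the covariance of independent series
            samp = sd_a * sd_b / np.sqrt(n - 1)
            assert abs(c) <= 3.0 * samp, (a, b)


class TestVarianceChangeDecomposition:
    def test_equal_betas_no_sensitivity_effect(self):
        rng = np.random.default_rng(8)
        nbp, d_ctl, beta, comps = _tiny_fit(rng)
        d_expa = {k: _anom(0.5 * v.values) for k, v in d_ctl.items()}
        out = decompose_variance_change(beta, beta, d_ctl, d_expa)
        for name in out:
            np.testing.assert_allclose(out[name]["sensitivity_effect"], 0.0,
                                       atol=1e-12)

    def test_equal_drivers_no_driver_effect(self):
        rng = np.random.default_rng(9)
        nbp, d_ctl, beta_ctl, comps = _tiny_fit(rng)
        nbp2, _, _, _ = _tiny_fit(rng)
        beta_expa = fit_monthwise_ols(nbp2, d_ctl)
        out = decompose_variance_change(beta_ctl, beta_expa, d_ctl, d_ctl)
        for name in out:
            np.testing.assert_allclose(out[name]["driver_variance_effect"],
                                       0.0, atol=1e-12)

    def test_telescoping_identity(self, fitted_system):
        out = decompose_variance_change(
            fitted_system["beta_ctl"], fitted_system["beta_expa"],
            fitted_system["drivers_ctl"], fitted_system["drivers_expa"])
        for name, terms in out.items():
            np.testing.assert_allclose(
                terms["driver_variance_effect"] + terms["sensitivity_effect"],
                terms["total_change"], atol=1e-12)


class TestGppRedBudget:
    def test_hand_example(self):
        """CTL GPP {1,-1}, ReD {1,-1}; ExpA both {0,0}: variance changes are
        -2, -2 and the covariance term contributes +4 (N-1 = 1)."""
        out = gpp_red_budget([1.0, -1.0], [1.0, -1.0], [0.0, 0.0], [0.0, 0.0])
        assert out["dvar_gpp"] == pytest.approx(-2.0)
        assert out["dvar_red"] == pytest.approx(-2.0)
        assert out["minus_2dcov"] == pytest.approx(4.0)
        assert out["dvar_nbp"] == pytest.approx(0.0, abs=1e-14)

    def test_constant_red_reduces_to_gpp(self):
        rng = np.random.default_rng(10)
        g_c, g_x = rng.normal(size=20), rng.normal(size=20)
        zeros = np.zeros(20)
        out = gpp_red_budget(g_c, zeros, g_x, zeros)
        assert out["dvar_nbp"] == pytest.approx(out["dvar_gpp"], rel=1e-12)

    def test_identical_experiments_all_zero(self):
        rng = np.random.default_rng(11)
        g, r = rng.normal(size=15), rng.normal(size=15)
        out = gpp_red_budget(g, r, g, r)
        for v in out.values():
            assert v == pytest.approx(0.0, abs=1e-14)


class TestHotspotClasses:
    def test_all_weak_when_no_change(self):
        z = np.zeros((2, 2))
        cls = hotspot_classes(z, z, z, thresholds=(0.1, 0.1))
        assert np.all(cls == 0)

    def test_strong_lac_cell(self):
        z = np.zeros((1, 2))
        dt = np.array([[-1.0, 0.0]])
        dv = np.array([[-1.0, 0.0]])
        cls = hotspot_classes(z, dt, dv, thresholds=(0.5, 0.5))
        assert cls[0, 0] == 3 and cls[0, 1] == 0

    def test_threshold_tie_is_not_hotspot(self):
        z = np.zeros((1, 1))
        dt = np.array([[-0.5]])
        cls = hotspot_classes(z, dt, np.zeros((1, 1)), thresholds=(0.5, 0.5))
        assert cls[0, 0] == 0

    def test_single_axis_classes_and_mask(self):
        z = np.zeros((1, 3))
        dt = np.array([[-1.0, 0.0, -1.0]])
        dv = np.array([[0.0, -1.0, 0.0]])
        mask = np.array([[True, True, False]])
        cls = hotspot_classes(z, dt, dv, thresholds=(0.5, 0.5),
                              land_mask=mask)
        assert cls[0, 0] == 1 and cls[0, 1] == 2 and cls[0, 2] == -1

    def test_missing_thresholds_error(self):
        z = np.zeros((1, 1))
        with pytest.raises(ValueError, match="threshold"):
            hotspot_classes(z, z, z, thresholds=None)


class TestSpreadBounds:
    def _profile(self, fractions):
        n = len(next(iter(fractions.values())))
        filled = {k: np.asarray(fractions.get(k, np.zeros(n)), float)
                  for k in ("SM", "LAC", "nonLAC", "R")}
        return ContributionProfile(list(range(n)), filled)

    def test_identical_replicates_zero_spread(self):
        p = self._profile({"SM": [0.2, 0.4]})
        sb = spread_bounds([p, p, p])
        assert np.max(sb.outer["SM"]) < 1e-15
        assert np.max(sb.inner["SM"]) < 1e-15

    def test_constant_offset_absorbed_by_inner(self):
        p1 = self._profile({"SM": [0.2, 0.4]})
        p2 = self._profile({"SM": [0.3, 0.5]})  # +0.1 at every level
        sb = spread_bounds([p1, p2])
        assert np.max(sb.inner["SM"]) < 1e-12
        np.testing.assert_allclose(sb.outer["SM"],
                                   np.std([0.2, 0.3], ddof=1), atol=1e-12)

    def test_crossed_replicates_hand_values(self):
        """Fractions {0.2, 0.4} vs {0.4, 0.2}: outer sd = inner sd ~ 0.1414
        at both levels (means coincide, demeaned values cross)."""
        p1 = self._profile({"SM": [0.2, 0.4]})
        p2 = self._profile({"SM": [0.4, 0.2]})
        sb = spread_bounds([p1, p2])
        expected = np.std([0.2, 0.4], ddof=1)
        np.testing.assert_allclose(sb.outer["SM"], expected, atol=1e-12)
        np.testing.assert_allclose(sb.inner["SM"], expected, atol=1e-12)
        np.testing.assert_allclose(sb.mean["SM"], [0.3, 0.3], atol=1e-12)

    def test_mismatched_ladders_error(self):
        p1 = self._profile({"SM": [0.2, 0.4]})
        p2 = ContributionProfile([0, 1, 2],
                                 {k: np.zeros(3) for k in
                                  ("SM", "LAC", "nonLAC", "R")})
        with pytest.raises(ValueError, match="ladder"):
            spread_bounds([p1, p2])

    def test_single_replicate_errors(self):
        p = self._profile({"SM": [0.2, 0.4]})
        with pytest.raises(ValueError, match="2 replicates"):
            spread_bounds([p])
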