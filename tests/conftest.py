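import numpy as np
import pytest

from lacvar import CouplingConfig, compute_anomalies, generate_pair
from lacvar.grid import GridGeometry, MonthlyField


@pytest.fixture(scope="session")
def default_pair():
    """Default stated-world experiment pair + truth (seed 7)."""
    return generate_pair(CouplingConfig(seed=7))


@pytest.fixture(scope="session")
def fitted_system(default_pair):
    """Anomalies, fitted CTL/ExpA sensitivities and components for the
    default pair."""
    from lacvar import fit_monthwise_ols, reconstruct_components
    from lacvar.synthetic import DRIVERS

    pair, truth = default_pair
    d_ctl = {k: compute_anomalies(pair.ctl[k])[0] for k in DRIVERS}
    d_expa = {k: compute_anomalies(pair.expa[k])[0] for k in DRIVERS}
    nbp_ctl = compute_anomalies(pair.ctl["NBP"])[0]
    nbp_expa = compute_anomalies(pair.expa["NBP"])[0]
    b_ctl = fit_monthwise_ols(nbp_ctl, d_ctl, experiment="CTL")
    b_expa = fit_monthwise_ols(nbp_expa, d_expa, experiment="ExpA")
    c_ctl = reconstruct_components(b_ctl, d_ctl, nbp=nbp_ctl, experiment="CTL")
    c_expa = reconstruct_components(b_expa, d_expa, nbp=nbp_expa,
                                    experiment="ExpA")
    return dict(pair=pair, truth=truth, drivers_ctl=d_ctl,
                drivers_expa=d_expa, nbp_ctl=nbp_ctl, nbp_expa=nbp_expa,
                beta_ctl=b_ctl, beta_expa=b_expa, comps_ctl=c_ctl,
                comps_expa=c_expa)


def make_field(values, lat=None, lon=None, area=None, mask=None,
               start_year=2000, units="1", name="x"):
    """Small MonthlyField helper for hand-built examples."""
    values = np.asarray(values, dtype=float)
    n_t, n_lat, n_lon = values.shape
    if lat is None:
        lat = np.linspace(-60, 60, n_lat) if n_lat > 1 else np.array([0.0])
    if lon is None:
        lon = np.linspace(10, 10 + 20 * (n_lon - 1), n_lon) if n_lon > 1 \
            else np.array([0.0])
    geo = GridGeometry(np.asarray(lat, float), np.asarray(lon, float),
                       cell_area=area, land_mask=mask)
    t = np.arange(n_t)
    return MonthlyField(geo, start_year + t // 12, t % 12 + 1, values,
                        units=units, name=name)
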