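"""Partition NBP variance into direct, coupling-mediated and non-coupled
contributions, from local to global scales.

The non-coupled T&VPD part applies the control sensitivities to the ExpA
meteorology (what T and VPD do when soil moisture cannot vary); the
coupling-mediated (LAC) part is the per-cell variance remainder.  The same
split is repeated after conservative aggregation to coarser grids.
"""

import numpy as np

from lacvar import (
    CouplingConfig,
    compute_anomalies,
    contribution_profile,
    fit_monthwise_ols,
    generate_pair,
    partition_t_vpd_lac,
    reconstruct_components,
    truth_contributions,
)
from lacvar.pipeline import default_levels
from lacvar.synthetic import DRIVERS

pair, truth = generate_pair(CouplingConfig(seed=0))
d_ctl = {k: compute_anomalies(pair.ctl[k])[0] for k in DRIVERS}
d_expa = {k: compute_anomalies(pair.expa[k])[0] for k in DRIVERS}
nbp = compute_anomalies(pair.ctl["NBP"])[0]

beta = fit_monthwise_ols(nbp, d_ctl, experiment="CTL")
comps = reconstruct_components(beta, d_ctl, nbp=nbp)
lac = partition_t_vpd_lac(beta, comps, d_expa)

geo = pair.geometry
levels = default_levels(*geo.shape)
prof = contribution_profile(comps, lac, geo, levels)

print("variance fractions by aggregation level (block factor):")
print(prof.as_frame().round(3))
est = {k: prof.fractions[k][0] for k in prof.fractions}
true = truth_contributions(truth, geo)
print("native-grid estimate vs generator truth:")
for k in est:
    print(f"  {k:>6}: estimated {est[k]:.3f}  true {true[k]:.3f}")
print(f"cells where the variance remainder was floored at 0: {lac.n_floored}")
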