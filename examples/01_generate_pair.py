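"""Generate a paired factorial experiment (CTL vs prescribed soil moisture).

Builds the default synthetic world — a control run with interactive soil
moisture and a twin in which soil-moisture anomalies are suppressed while
every other random draw is identical — and shows the factorial contrast in
global annual NBP variability.
"""

import numpy as np

from lacvar import CouplingConfig, generate_pair, region_mean

pair, truth = generate_pair(CouplingConfig(seed=0))

for name, exp in [("CTL", pair.ctl), ("ExpA", pair.expa)]:
    s = region_mean(exp["NBP"]).values.reshape(-1, 12).mean(axis=1)
    print(f"{name}: global annual NBP sigma = {s.std(ddof=1):.3f} "
          f"(anomaly units)")

dT = pair.ctl["T"].values - pair.expa["T"].values
print(f"T difference sd (the coupling-driven part): {dT.std():.3f} K")
print("The ExpA twin loses most NBP variability because both the direct")
print("soil-water effect and the coupling-amplified T/VPD anomalies vanish.")
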