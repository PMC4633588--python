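"""Population viability under apparent vs residency-adjusted survival.

Apparent survival Φ from mark-recapture undercounts survivors that emigrated;
dividing by residency r gives adjusted survival S = Φ/r. The two-sex
individual-based simulator projects both parameterizations 1000 times for a
century (N0 = 50 at stable stage, K = 200).
"""

from platypus_popdyn import (
    adjusted_scenario,
    apparent_scenario,
    leslie_lambda,
    run_pva,
    summarize_pva,
)

for label, factory in (("apparent", apparent_scenario), ("adjusted", adjusted_scenario)):
    config = factory(seed=11, iterations=1000, years=100)
    lam, ln_lam = leslie_lambda(config)
    result = run_pva(config)
    out = summarize_pva(result, [20, 50, 100])
    med = out["median_time_to_extinction"]
    print(f"{label:9s} survival: deterministic lambda {lam:.3f}; "
          f"stochastic r {result.r_mean:+.3f} ± {result.r_sd:.3f}")
    print(f"          extinction by year 20/50/100: "
          f"{out['extinction_probability'][20]:.0%}/"
          f"{out['extinction_probability'][50]:.0%}/"
          f"{out['extinction_probability'][100]:.0%}; "
          f"median extinction year {med if med else 'beyond horizon'}")
print("-> taking apparent survival at face value predicts rapid collapse;")
print("   correcting for emigration yields a near-stationary population whose")
print("   residual risk comes from demographic noise at small population size.")
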