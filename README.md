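# platypus-popdyn

Mark-recapture demography and population viability analysis for platypus
(*Ornithorhynchus anatinus*) populations — and, more generally, for any
pool-structured river population surveyed annually over decades.

The package is aimed at quantitative ecologists who hold long-term
capture-record tables (animal id, date, pool, sex, age class, weight,
lactation status, netting effort) plus a river-flow series, and want to go
from those raw records all the way to extinction-risk estimates.

## What it computes

1. **Apparent survival and detection (CJS).** Conditioning on first capture,
   each encounter history contributes
   `P(h) = ∏ Φ_t [p_{t+1} or (1−p_{t+1})] · χ_l`, with the unobserved tail
   `χ_t = (1−Φ_t) + Φ_t (1−p_{t+1}) χ_{t+1}`, `χ_T = 1`. Φ and p are logit-linear
   in sex, time-varying age class, body weight (grams, with raw quadratics),
   cumulative river flow over 1/6/12/24-month look-backs, and netting effort.
   Candidate models are ranked by AICc (effective sample size = release
   events) and model-averaged over the 99% cumulative Akaike-weight set.
   Detection-corrected counts `N̂_t = count_t / p̂_t` give abundance trends.
2. **Movement and residency.** Consecutive recaptures yield per-class pool
   residency `r` with exact Beta(1+x, 1+n−x) posteriors and bootstrap
   movement-distance intervals.
3. **Survival adjustment.** Apparent survival confounds death with
   emigration: adjusted survival is `S = Φ / r`, with dispersal `d = 1 − r`.
4. **Viability (PVA).** A two-sex, age-classed stochastic simulator
   (breed → die → disperse → age → truncate to K) with polygynous breeding
   pools, litters of 1–2 (mean 1.5), first breeding at age 2 and maximum age
   21, reporting the stochastic growth rate
   `r̄ = mean ln(N_{t+1}/N_t)` and extinction probabilities by horizon.
   A female Leslie matrix supplies the deterministic λ oracle.
5. **Sensitivity.** Latin-hypercube scenarios over the five class mortalities
   and disperser transit survival, smoothed per parameter with a penalized
   cubic spline whose penalty minimizes `GCV(λ) = n·RSS/(n − tr H)²`, with
   ±2SE bands and threshold read-outs (e.g. the lowest adult-female survival
   compatible with persistence).
6. **Bayesian life-history summaries.** Binomial–Beta proportion tests,
   a semi-conjugate Gibbs linear model for weight/length contrasts, Poisson
   regression of lactating counts against flow, and breeding indices.

No field data ship with the package: `synthetic_data` generates
ground-truthed datasets with the same statistical structure (pool-resident
Markov movement, logit-linear detection, class-specific survival and
weights), so every stage is testable end to end.

## Worked example

```python
from platypus_popdyn import apparent_scenario, adjusted_scenario, run_pva, summarize_pva

for label, factory in (("apparent", apparent_scenario), ("adjusted", adjusted_scenario)):
    result = run_pva(factory(seed=11, iterations=1000, years=100))
    out = summarize_pva(result, [100])
    print(label, round(result.r_mean, 3), out["extinction_probability"][100])
```

prints

```
apparent -0.24 1.0
adjusted -0.036 0.651
```

Read: taking apparent survival at face value (adult females Φ = 0.76, adult
males Φ = 0.57, juveniles far lower) the population collapses — the mean
stochastic growth rate is −0.24/year and every replicate is extinct within a
century (median extinction year 17). Correcting the same estimates for pool
residency (S = Φ/r) lifts adult-female survival to 0.89 and the population
becomes near-stationary (r ≈ −0.04); the residual extinction risk reflects
demographic stochasticity and intermittent shortage of breeding males at the
small simulated scale (50 animals, ceiling 200). `examples/` contains one
script per capability with the numbers each prints explained inline.

A full pipeline (simulate → CJS → residency → adjusted rates → PVA →
sensitivity) runs from a YAML config:

```bash
platypus-popdyn demo --out out/ --seed 1
```

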