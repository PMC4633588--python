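# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic-data tests do and do not demonstrate.

## Data model and occasions

Capture records are one row per capture event; pools are reduced to a 1-D
chainage (metres along the channel), so "distance moved" is always
along-channel distance between pool chainages. Survey occasions are 12-month
windows starting 1 July, so a single December–March field season never
straddles two occasions; windows are half-open `[start, end)` and partition
the study span. Occasion covariates are the summed net-hours of the unique
(date, pool) surveys inside the window and cumulative river flow (GL) over
the 1/6/12/24 months ending at the window midpoint, plus the maximum monthly
flows over January–December and January–April of the midpoint's calendar
year. A flow series that fails to cover a look-back raises a coverage error
rather than silently truncating.

## CJS likelihood and model selection

The likelihood conditions on first capture. For animal *i* first caught at
occasion *f* and last seen at *l*:

    ln L_i = Σ_{t=f}^{l-1} [ ln Φ_{i,t} + y_{i,t+1} ln p_{i,t+1} + (1−y_{i,t+1}) ln(1−p_{i,t+1}) ] + ln χ_{i,l}
    χ_{i,t} = (1−Φ_{i,t}) + Φ_{i,t} (1−p_{i,t+1}) χ_{i,t+1},   χ_{i,T} = 1

Both parameters are logit-linear. Interval *t* → *t+1* takes individual
covariates (sex, time-varying age class, per-stage mean weight) at occasion
*t* and occasion covariates (flows, effort) at occasion *t+1*, i.e. the
conditions accumulated over the interval; detection at occasion *s* uses the
covariates of occasion *s*. Weight enters in raw grams and quadratics are raw
squares (not orthogonalized), so coefficients are directly on the
grams/GL/net-hour scale. Age class uses three bins — juvenile, sub-adult,
adult — as additive offsets with juvenile females as the reference; the class
sequence is propagated forward from the minimum age implied at first capture
(females adult after year 1; males sub-adult in years 1–2, adult after year
2; adults at first capture enter at their minimum age). Multiple captures in
one occasion collapse to a single encounter, and each animal contributes one
mean weight per life stage.

Fitting is quasi-Newton (BFGS) with internally standardized columns (reported
coefficients are back-transformed to the raw scale), a zero start plus
jittered restarts, and finite-difference gradients. Because such gradients
bottom out near 1e-4, convergence is declared when the optimizer succeeds
*or* the scaled gradient's max-norm falls below 1e-2 at the best point; the
covariance comes from a central-difference Hessian, with standard errors
flagged unavailable if it is singular. AICc uses the number of release events
(captures not on the final occasion) as the effective sample size — the usual
mark-recapture convention; since any other choice shifts all models' AICc
almost equally, rankings and weights are insensitive to it. Model averaging
keeps the top-ranked set reaching 99% cumulative Akaike weight, renormalizes,
and averages real-scale (inverse-logit) predictions. AICc ties are broken
toward fewer parameters. Abundance correction is Horvitz–Thompson
(`count/p̂`) with an OLS slope on the occasion index.

## Residency and the survival adjustment

Residency *r* per sex–age class is the posterior mean of a Binomial–Beta(1,1)
model over same-pool counts among consecutive (cross-occasion) recapture
pairs; the pair's class is the class at the earlier capture, when the
movement decision was made. "Same pool" means identical pool id, not a
distance threshold. Adjusted survival is `S = Φ/r`, capped at 1 with a
warning when `Φ > r`; dispersal is `d = 1 − r`. Distance means carry
10,000-resample percentile-bootstrap intervals.

## Bayesian building blocks

Proportions use the exact Beta(1+x, 1+n−x) posterior (equal-tailed
intervals); two-group differences use 100,000 paired posterior draws. The
Gaussian linear model is sampled by Gibbs alternation between the exact full
conditionals β | σ² ~ N(β̂_OLS, σ²(XᵀX)⁻¹) (flat coefficient prior) and
σ² | β ~ IG((c₀+n)/2, (d₀+RSS)/2) with c₀ = d₀ = 0.001; defaults are 10,000
draws after 1,000 burn-in, thinned by 5, with split-half and lag-1
autocorrelation diagnostics. The Poisson regression (log link, log exposure
offset) is sampled by random-walk Metropolis with the proposal covariance
taken from the curvature at the posterior mode. Its coefficients get
independent N(0, 25²) priors rather than strictly flat ones: a flat prior is
improper when the predictor is degenerate (e.g. constant), while at the
plausible effect scale (|slope| ≲ 1) the N(0, 25²) prior is numerically
indistinguishable from flat. Decade summaries use the fixed bins
1973–1983 / 1984–1993 / 1994–2003 / 2004–2014, counting each female once per
year (so possibly several times per decade).

## Viability simulator

The simulator is a two-sex, age-classed stochastic projection with event
order breed → die → disperse → age → truncate, i.e. a post-breeding annual
census. Defaults: 62% of adult females and 38% of adult males enter the
breeding pools each year (independent Bernoulli draws, so the male pool can
be empty in a small population, in which year no breeding occurs); litters
are 1 or 2 young with mean 1.5 (P(2) = 0.5, the only two-point distribution
on {1,2} with that mean); births are 50:50; both sexes first breed at age 2;
animals exceeding age 21 die. Mortality is class-specific over juvenile
females (first year), adult females (age ≥ 1), juvenile males (first year),
sub-adult males (age 1→2) and adult males (age ≥ 2). Dispersal is temporary
emigration from a single population: each survivor disperses with its class
probability `d` and dies in transit with probability `1 − s_disp` (default
`s_disp = 1`, making dispersal demographically neutral). Truncation to the
ceiling K removes individuals uniformly at random (multivariate
hypergeometric across age–sex cells). Environmental variation is not
modelled; all variance is demographic.

Individuals within a sex–age class are exchangeable (no individual
heterogeneity), so the implementation tracks exact integer counts per
(sex, age) cell with binomial draws — the identical stochastic process to
simulating each animal, vectorised across Monte Carlo iterations. One seeded
`numpy` Generator drives everything; identical seeds give bit-identical
results.

The stochastic growth rate is the pooled mean of `ln(N_{t+1}/N_t)` over all
iteration-years with `N_t > 0` and `N_{t+1} > 0`; extinction time is the
first census at zero. The deterministic oracle is a female-only Leslie matrix
over census ages 1..21 whose first-row fecundities are
(breeding fraction × mean litter × daughter fraction × first-year survival) —
the first-year survival factor is required for the post-breeding census to
match the simulator, and an independent Euler–Lotka bisection confirms its λ.
The initial population is placed at the integerized (largest-remainder)
stable stage of the two-sex projection.

Scenario presets use published-scale mortalities: apparent
73/24/87/62/43% (juvenile F / adult F / juvenile M / sub-adult M / adult M)
with dispersal off, and residency-adjusted 71/11/77/43/23% with class
dispersal fractions 15.4/14.5/55/38/26% and full transit survival. Defaults
N0 = 50 at stable stage, K = 200, 1000 iterations × 100 years. At this small
scale two mechanisms dominate adjusted-scenario extinction risk even though
the deterministic λ ≈ 0.998: occasional empty male breeding pools (with ~5–8
adult males, a 2–10% annual chance of zero recruitment under the Bernoulli
pool rule) and plain demographic stochasticity. Simulated 100-year extinction
probabilities are therefore substantially higher than a female-driven
reproduction accounting at a larger population scale would give; users
comparing against such analyses should treat the extinction probability — not
the growth rate, which is insensitive — as scale-dependent.

## Sensitivity analysis

Scenario inputs are a Latin-hypercube sample (for uniform marginal coverage
at modest n) over the five class mortalities and `s_disp`, each on [0,1] by
default, with one child seed per row; defaults are 500 scenarios × 200
iterations, and reduced sizes are used throughout the test suite and demo
pipeline. The response is median time to extinction, with censored runs
assigned the horizon before the log transform (recorded in the table
metadata); curves are smoothed per parameter — no interactions — by a cubic
B-spline (interior knots at up to 30 quantiles of distinct x) penalized by
the exact integrated squared second derivative, with λ minimizing
`GCV(λ) = n·RSS/(n − tr H)²` over a descending log grid refined by
golden-section search. Ties (e.g. interpolable noiseless signals, where RSS
is numerically zero for every λ) resolve toward the larger λ, so a noiseless
linear signal correctly returns edf ≈ 2; the grid is capped at a relative
penalty of 1e9 to keep the penalized system well conditioned. Pointwise
standard errors use σ̂² = RSS/(n − edf) and the sandwich
`B(BᵀB+λΩ)⁻¹BᵀB(BᵀB+λΩ)⁻¹Bᵀ`. Thresholds are read off a 512-point grid as the
smallest parameter value (survival scale for mortality axes) where the smooth
meets the criterion, bracketed by the ±2SE band's crossings.

## Synthetic data: what it emulates and what it does not

The generator simulates a 15-pool reach with geometric-decay movement
(exponential kernel in chainage distance, 500 m scale — chosen to reproduce
a heavy-tailed movement pattern in which a few percent of consecutive
recaptures exceed 2 km), class-specific true survival (defaults
0.29/0.89/0.23/0.57/0.77), residency (0.93/0.85/0.43/0.66/0.74), Table-scale
body weights drawn once per life stage, lognormal monthly flows (median 3 GL,
σ_log = 1), a 62% adult-female breeding rate with litters of mean 1.5 (which
puts the default population near stationarity, λ ≈ 1, so multi-decade
datasets neither crash nor explode), and logit-linear detection with
coefficients on the published scale. Offspring of a season enter the catchable
population the following year as juveniles.

Because all 15 simulated pools are surveyed, no animal permanently leaves the
study area: fitted apparent survival recovers the configured *true* survival,
and the Φ-vs-S gap of a real study (driven by emigration past the study
bounds) is not emulated. Passing recovery tests therefore demonstrate the
estimators, not the field-estimation biases. The generator also omits
within-year capture dynamics (occasions are annual), environmental
stochasticity in vital rates, tag loss, and individual heterogeneity in
detection or survival.

## Known limitations

- Single open population: no multi-state models, no river-network
  metapopulation, no overdispersion (ĉ) adjustment.
- Detection heterogeneity beyond the modelled covariates will bias
  Horvitz–Thompson abundance upward or downward as in any CMR analysis.
- The PVA has no inbreeding depression, catastrophes, or environmental
  variance; extinction probabilities are demographic-only and depend strongly
  on the chosen N0 and K (see above).
- GAM-style significance tables (per-parameter F statistics) are out of
  scope; the sensitivity module reports smooths, edf and thresholds only.
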