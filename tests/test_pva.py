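import numpy as np
import pytest
from dataclasses import replace

from platypus_popdyn import (
    PVAConfig,
    adjusted_scenario,
    apparent_scenario,
    derive_vital_rates,
    leslie_lambda,
    run_pva,
    stable_stage,
    summarize_pva,
    vital_rates_from_mortality,
)
from platypus_popdyn.io_data_model import FIVE_CLASSES
from platypus_popdyn.pva import ADJUSTED_MORTALITY


def flat(phi_val, r_val):
    return {c: phi_val for c in FIVE_CLASSES}, {c: r_val for c in FIVE_CLASSES}


class TestVitalRates:
    def test_adjusted_adult_mortalities(self):
        phi, r = flat(0.5, 0.9)
        phi["female_adult"], r["female_adult"] = 0.76, 1 - 0.145
        phi["male_adult"], r["male_adult"] = 0.57, 0.74
        vr = derive_vital_rates(phi, r)
        assert round(vr.mortality["female_adult"] * 100) == 11
        assert round(vr.mortality["male_adult"] * 100) == 23

    def test_full_residency_is_identity(self):
        phi, r = flat(0.42, 1.0)
        vr = derive_vital_rates(phi, r)
        assert all(vr.survival[c] == pytest.approx(0.42) for c in FIVE_CLASSES)
        assert all(vr.dispersal[c] == 0.0 for c in FIVE_CLASSES)

    def test_capping_warns(self):
        phi, r = flat(0.9, 0.5)
        with pytest.warns(UserWarning, match="capped"):
            vr = derive_vital_rates(phi, r)
        assert all(v == 1.0 for v in vr.survival.values())

    def test_zero_residency_rejected(self):
        phi, r = flat(0.5, 0.5)
        r["male_juvenile"] = 0.0
        with pytest.raises(ValueError):
            derive_vital_rates(phi, r)


def euler_lotka_lambda(s_juv, s_ad, m, first_age=2, max_age=21):
    """Independent oracle: bisection on 1 = Σ λ^{-x} l_x m over breeding ages."""

    def f(lam):
        total = 0.0
        for x in range(first_age, max_age + 1):
            lx = s_juv * s_ad ** (x - 1)
            total += lam ** (-x) * lx * m
        return total - 1.0

    lo, hi = 0.2, 2.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestLeslie:
    def test_matches_euler_lotka_oracle(self):
        cfg = adjusted_scenario()
        lam, ln_lam = leslie_lambda(cfg)
        m = 0.62 * 1.5 * 0.5
        oracle = euler_lotka_lambda(0.29, 0.89, m)
        assert lam == pytest.approx(oracle, abs=1e-6)
        assert 0.97 <= lam <= 1.03

    def test_lambda_increases_with_adult_female_survival(self):
        lams = []
        for s in (0.70, 0.75, 0.80, 0.85, 0.90):
            mort = dict(ADJUSTED_MORTALITY, female_adult=1 - s)
            cfg = PVAConfig(vital_rates=vital_rates_from_mortality(mort))
            lams.append(leslie_lambda(cfg)[0])
        assert all(a < b for a, b in zip(lams, lams[1:]))


class TestStableStage:
    def test_counts_sum_to_initial_size(self):
        cfg = adjusted_scenario(initial_size=73)
        ss = stable_stage(cfg)
        assert ss["female"].sum() + ss["male"].sum() == 73

    def test_counts_track_eigenvector_shares(self):
        cfg = adjusted_scenario(initial_size=500)
        ss = stable_stage(cfg)
        counts = np.concatenate([ss["female"][1:], ss["male"][1:]])
        shares = counts / counts.sum() * 500
        assert np.max(np.abs(counts - shares)) <= 1.0 + 1e-9


class TestRunPVA:
    def test_total_mortality_means_immediate_extinction(self):
        vr = vital_rates_from_mortality({c: 1.0 for c in FIVE_CLASSES})
        cfg = PVAConfig(vital_rates=vr, iterations=50, years=5, seed=1)
        res = run_pva(cfg)
        assert (res.extinction_time == 1).all()

    def test_immortal_cohort_persists_until_age_limit(self):
        vr = vital_rates_from_mortality({c: 0.0 for c in FIVE_CLASSES})
        A = 21
        female = np.zeros(A + 1, dtype=int)
        female[1] = 30
        male = np.zeros(A + 1, dtype=int)
        cfg = PVAConfig(
            vital_rates=vr, breeding_pool_female=0.0, carrying_capacity=None,
            iterations=3, years=25, seed=1, initial_size=30,
            initial_counts={"female": female, "male": male},
        )
        res = run_pva(cfg)
        # constant until the cohort (age 1 at the start) exceeds age 21
        assert (res.trajectories[:, :21] == 30).all()
        assert (res.trajectories[:, 21:] == 0).all()

    def test_same_seed_is_bit_identical(self):
        cfg = adjusted_scenario(iterations=40, years=30, seed=9)
        a, b = run_pva(cfg), run_pva(cfg)
        assert (a.trajectories == b.trajectories).all()

    def test_full_transit_survival_equals_no_dispersal(self):
        base = adjusted_scenario(iterations=40, years=30, seed=9)
        no_disp = replace(
            base,
            vital_rates=replace(base.vital_rates, dispersal={c: 0.0 for c in FIVE_CLASSES}),
        )
        assert (run_pva(base).trajectories == run_pva(no_disp).trajectories).all()

    def test_zero_transit_survival_recovers_apparent_survival(self):
        # with s_disp = 0, realized survival frequency ≈ S_y (1 - d_y) = Φ_y
        phi, residency = 0.7, 0.8
        vr = derive_vital_rates(
            {c: phi for c in FIVE_CLASSES}, {c: residency for c in FIVE_CLASSES}, s_disp=0.0
        )
        A = 21
        female = np.zeros(A + 1, dtype=int)
        female[5] = 10_000
        cfg = PVAConfig(
            vital_rates=vr, breeding_pool_female=0.0, carrying_capacity=None,
            iterations=1, years=1, seed=3, initial_size=10_000,
            initial_counts={"female": female, "male": np.zeros(A + 1, dtype=int)},
        )
        res = run_pva(cfg)
        realized = res.trajectories[0, 1] / 10_000
        assert realized == pytest.approx(phi, abs=0.02)

    def test_growth_cannot_exceed_carrying_capacity(self):
        cfg = adjusted_scenario(iterations=20, years=30, seed=2, carrying_capacity=80)
        res = run_pva(cfg)
        assert res.trajectories.max() <= 80


class TestSummaries:
    def test_no_extinctions_reported_censored(self):
        vr = vital_rates_from_mortality({c: 0.0 for c in FIVE_CLASSES})
        cfg = PVAConfig(vital_rates=vr, iterations=10, years=10, seed=1, initial_size=100,
                        carrying_capacity=None)
        out = summarize_pva(run_pva(cfg), [5, 10])
        assert out["extinction_probability"][10] == 0.0
        assert out["median_time_to_extinction"] is None
        assert out["censored"]

    def test_extinction_probability_monotone_in_horizon(self):
        cfg = apparent_scenario(iterations=100, years=60, seed=4)
        out = summarize_pva(run_pva(cfg), [10, 20, 40, 60])
        probs = list(out["extinction_probability"].values())
        assert all(a <= b for a, b in zip(probs, probs[1:]))

    def test_all_extinct_at_known_year(self):
        vr = vital_rates_from_mortality({c: 1.0 for c in FIVE_CLASSES})
        cfg = PVAConfig(vital_rates=vr, iterations=20, years=5, seed=1)
        out = summarize_pva(run_pva(cfg), [1, 3, 5])
        assert out["median_time_to_extinction"] == 1.0
        assert out["extinction_probability"][1] == 1.0
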