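import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platypus_popdyn import (
    CJSDesign,
    aicc,
    akaike_weights,
    build_capture_histories,
    cjs_negloglik,
    estimate_abundance_trend,
    fit_cjs,
    predict_from_coefficients,
    predict_real,
    rank_and_average,
)
from platypus_popdyn.cjs import cjs_loglik_per_individual
from platypus_popdyn.io_data_model import CaptureRecord
import datetime as dt

from .conftest import (
    all_histories,
    enumerate_history_probability,
    make_history_matrix,
    simulate_constant_histories,
)

CONST = CJSDesign((), ())


def logit(x):
    return math.log(x / (1 - x))


class TestLikelihood:
    def test_two_occasion_histories_have_closed_forms(self):
        chm = make_history_matrix([[1, 1]])
        # seen again: phi * p
        assert cjs_negloglik(chm, CONST, [logit(0.5), logit(0.5)]) == pytest.approx(
            -math.log(0.25), abs=1e-12
        )
        chm = make_history_matrix([[1, 0]])
        # never seen again: (1 - phi) + phi (1 - p)
        assert cjs_negloglik(chm, CONST, [logit(0.5), logit(0.5)]) == pytest.approx(
            -math.log(0.75), abs=1e-12
        )

    @pytest.mark.parametrize("T", [2, 3, 4])
    def test_matches_enumeration_oracle_with_time_varying_rates(self, T):
        rng = np.random.default_rng(17)
        for _ in range(5):
            phi = rng.uniform(0.2, 0.95, T - 1)
            p = rng.uniform(0.1, 0.9, T - 1)
            hists = all_histories(T)
            chm = make_history_matrix(hists)
            ll = cjs_loglik_per_individual(
                chm, np.tile(phi, (len(hists), 1)), np.tile(p, (len(hists), 1))
            )
            probs = np.exp(ll)
            for h, pr in zip(hists, probs):
                oracle = enumerate_history_probability(h, 0, phi, p)
                assert pr == pytest.approx(oracle, abs=1e-10)
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_rejects_non_finite_parameters(self):
        chm = make_history_matrix([[1, 1]])
        with pytest.raises(ValueError):
            cjs_negloglik(chm, CONST, [np.nan, 0.0])


class TestModelSelection:
    def test_aicc_formula(self):
        assert aicc(0.0, 0, 10) == pytest.approx(0.0)
        k, ess, ll = 13, 868, -1120.22
        assert aicc(ll, k, ess) == pytest.approx(-2 * ll + 26 + 364 / 854)
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)

    def test_aicc_approaches_aic_with_sample_size(self):
        vals = [aicc(-100.0, 5, ess) for ess in (20, 100, 1000, 100_000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(210.0, abs=0.01)

    def test_equal_models_share_weight(self):
        w = akaike_weights([100.0, 100.0])
        assert np.allclose(w, [0.5, 0.5])

    @given(st.lists(st.floats(0, 50), min_size=1, max_size=8), st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weights_normalize_and_shift_invariant(self, deltas, shift):
        w = akaike_weights(deltas)
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w, akaike_weights(np.asarray(deltas) + shift))


class TestFitting:
    def test_single_occasion_is_rejected(self):
        chm = make_history_matrix([[1, 1]])
        chm.encounter = chm.encounter[:, :1]
        with pytest.raises(ValueError):
            fit_cjs(chm, CONST)

    def test_recovers_constant_rates(self):
        rng = np.random.default_rng(21)
        chm = simulate_constant_histories(800, 15, phi=0.8, p=0.6, rng=rng)
        fit = fit_cjs(chm, CONST, n_starts=2)
        from scipy.special import expit

        phi_hat, p_hat = expit(fit.beta)
        assert abs(phi_hat - 0.8) < 0.05
        assert abs(p_hat - 0.6) < 0.08
        assert fit.se_available

    def test_positive_effort_effect_is_detected(self):
        # detection driven up by effort: fitted coefficient positive, CI excludes 0
        rng = np.random.default_rng(33)
        n, T = 1000, 12
        effort = rng.uniform(0.0, 10.0, T)
        from scipy.special import expit as sigmoid

        enc = np.zeros((n, T), dtype=int)
        first = rng.integers(0, T - 1, size=n)
        for i in range(n):
            enc[i, first[i]] = 1
            for t in range(first[i], T - 1):
                if rng.random() >= 0.85:
                    break
                if rng.random() < sigmoid(-2.0 + 0.4 * effort[t + 1]):
                    enc[i, t + 1] = 1
        chm = make_history_matrix(enc)
        chm.occasion_covariates["effort"] = effort
        fit = fit_cjs(chm, CJSDesign((), ("effort",)), n_starts=2)
        row = fit.coefficients.set_index("term").loc["p:effort"]
        assert row.estimate > 0
        assert row.lcl > 0

    def test_nesting_never_worsens_loglik(self, small_chm):
        f0 = fit_cjs(small_chm, CONST, n_starts=2)
        f1 = fit_cjs(small_chm, CJSDesign(("sex",), ()), n_starts=2)
        assert f1.loglik >= f0.loglik - 1e-6


class TestRankAverage:
    def test_table_orders_and_retains(self, small_chm):
        fits = [
            fit_cjs(small_chm, CONST, n_starts=2),
            fit_cjs(small_chm, CJSDesign(("age",), ()), n_starts=2),
        ]
        mt = rank_and_average(fits)
        assert (mt.table["delta_AICc"].diff().dropna() >= 0).all()
        assert mt.table["weight"].sum() == pytest.approx(1.0)
        pred = mt.predict({"sex": "female", "age_class": "adult", "weight": 900.0})
        assert 0 < pred["phi"] < 1 and 0 < pred["p"] < 1

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            rank_and_average([])


class TestPrediction:
    def test_null_coefficients_give_half(self):
        assert predict_from_coefficients({"intercept": 0.0}, {}) == pytest.approx(0.5)

    def test_missing_covariate_is_named(self, small_chm):
        fit = fit_cjs(small_chm, CJSDesign((), ("effort",)), n_starts=2)
        with pytest.raises(KeyError, match="effort"):
            predict_real(fit, {"sex": "female", "age_class": "adult"})

    def test_interval_is_ordered(self, small_chm):
        fit = fit_cjs(small_chm, CJSDesign((), ("effort",)), n_starts=2)
        est, lo, hi = predict_real(fit, {"effort": 100.0})["p"]
        assert lo <= est <= hi


class TestHistories:
    def test_within_occasion_captures_collapse(self, small_dataset):
        occ = small_dataset["occasions"]
        base = dict(pool_id="p1", sex="female", age_class="adult", weight_g=900.0, effort_hours=5.0)
        records = [
            CaptureRecord(animal_id="z", date=dt.date(occ[0].start.year, 12, 1), **base),
            CaptureRecord(animal_id="z", date=dt.date(occ[0].start.year + 1, 2, 1), **base),
        ]
        chm = build_capture_histories(records, occ)
        assert chm.encounter.sum() == 1

    def test_juvenile_female_becomes_adult_next_year(self, small_dataset):
        occ = small_dataset["occasions"]
        records = [
            CaptureRecord(
                animal_id="z", date=dt.date(occ[2].start.year, 12, 1), pool_id="p1",
                sex="female", age_class="juvenile", weight_g=650.0, effort_hours=5.0,
            )
        ]
        chm = build_capture_histories(records, occ)
        assert chm.age_code[0, 2] == 0  # juvenile at first capture
        assert (chm.age_code[0, 3:] == 2).all()  # adult from the next year on
        assert (np.diff(chm.age_code[0]) >= 0).all()

    def test_row_sums_match_generator_capture_counts(self, small_dataset, small_chm):
        book = small_dataset["book"]
        counts = {f"a{i:05d}": len(v) for i, v in book.per_animal_capture_years.items()}
        for aid, row in zip(small_chm.animal_ids, small_chm.encounter):
            assert row.sum() == counts[aid]


class TestAbundance:
    def test_perfect_detection_is_identity(self):
        counts = np.array([10.0, 12, 8, 15])
        res = estimate_abundance_trend(counts, np.ones(4))
        assert np.allclose(res.adjusted, counts)

    def test_constant_counts_give_zero_slope(self):
        res = estimate_abundance_trend([10] * 5, [0.5] * 5)
        assert np.allclose(res.adjusted, 20.0)
        assert res.slope == pytest.approx(0.0, abs=1e-10)
        assert (res.adjusted >= 10).all()

    def test_zero_detection_rejected(self):
        with pytest.raises(ValueError):
            estimate_abundance_trend([10.0], [0.0])

    def test_horvitz_thompson_recovery_is_unbiased(self):
        rng = np.random.default_rng(8)
        true_n = np.array([120, 100, 90, 110, 130, 80, 95, 105])
        p = np.array([0.3, 0.5, 0.4, 0.6, 0.2, 0.7, 0.45, 0.55])
        ratios = []
        for _ in range(50):
            counts = rng.binomial(true_n, p)
            res = estimate_abundance_trend(counts, p)
            ratios.append(np.mean(res.adjusted / true_n))
        assert abs(np.mean(ratios) - 1.0) < 0.05
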