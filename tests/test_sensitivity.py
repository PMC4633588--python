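import numpy as np
import pandas as pd
import pytest

from platypus_popdyn import (
    adjusted_scenario,
    fit_gcv_spline,
    run_sensitivity,
    sample_scenarios,
    threshold_report,
)
from platypus_popdyn.io_data_model import FIVE_CLASSES
from platypus_popdyn.sensitivity import SCENARIO_DIMENSIONS, spline_edf


class TestScenarioSampling:
    def test_latin_hypercube_stratifies_each_margin(self):
        df = sample_scenarios(n=100, seed=1)
        for dim in SCENARIO_DIMENSIONS:
            bins = np.floor(df[dim].to_numpy() * 10).astype(int)
            counts = np.bincount(np.clip(bins, 0, 9), minlength=10)
            assert (counts == 10).all()

    def test_degenerate_range_held_constant(self):
        with pytest.warns(UserWarning, match="degenerate"):
            df = sample_scenarios({"dispersal_success": (0.5, 0.5)}, n=20, seed=1)
        assert (df["dispersal_success"] == 0.5).all()

    def test_same_seed_same_table(self):
        a = sample_scenarios(n=30, seed=7)
        b = sample_scenarios(n=30, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError):
            sample_scenarios({"bogus": (0, 1)}, n=5)


def _scenario_row(mortalities, s_disp, seed=1, scenario=0):
    row = {"scenario": scenario, "dispersal_success": s_disp, "seed": seed}
    row.update({f"mortality_{c}": m for c, m in mortalities.items()})
    return row


class TestRunSensitivity:
    def test_extreme_rows_have_known_outcomes(self):
        base = adjusted_scenario(years=30, seed=0)
        rows = [
            _scenario_row({c: 1.0 for c in FIVE_CLASSES}, 1.0, scenario=0),
            _scenario_row({c: 0.0 for c in FIVE_CLASSES}, 1.0, scenario=1),
        ]
        out = run_sensitivity(pd.DataFrame(rows), base, iterations_per_scenario=20)
        assert out.loc[0, "time_to_extinction"] == 1.0
        assert not out.loc[0, "censored"]
        assert out.loc[1, "time_to_extinction"] == 30.0
        assert out.loc[1, "censored"]

    def test_extinction_time_monotone_in_adult_female_mortality(self):
        base = adjusted_scenario(years=60, seed=0)
        rows = []
        from platypus_popdyn.pva import ADJUSTED_MORTALITY

        for k, m in enumerate((0.05, 0.25, 0.45, 0.65, 0.85)):
            mort = dict(ADJUSTED_MORTALITY, female_adult=m)
            rows.append(_scenario_row(mort, 1.0, seed=11, scenario=k))
        out = run_sensitivity(pd.DataFrame(rows), base, iterations_per_scenario=400)
        tte = out["time_to_extinction"].to_numpy()
        assert all(a >= b - 1.0 for a, b in zip(tte, tte[1:]))  # small MC slack
        assert tte[0] > tte[-1]


class TestGCVSpline:
    def test_noiseless_line_gives_two_degrees_of_freedom(self):
        x = np.linspace(0, 1, 50)
        y = 2 * x - 1
        fit = fit_gcv_spline(x, y)
        assert fit.edf == pytest.approx(2.0, abs=0.1)
        assert np.max(np.abs(fit.predict(x) - y)) < 1e-6

    def test_recovers_sine_signal(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 200)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.1, 200)
        fit = fit_gcv_spline(x, y)
        grid = np.linspace(0, 1, 101)
        rmse = np.sqrt(np.mean((fit.predict(grid) - np.sin(2 * np.pi * grid)) ** 2))
        assert rmse < 0.1

    def test_selected_penalty_beats_exhaustive_grid(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 120)
        y = np.cos(3 * x) + rng.normal(0, 0.2, 120)
        fit = fit_gcv_spline(x, y)
        # an exhaustive 1000-point grid cannot find a materially better GCV
        best = min(
            _gcv_of(x, y, lam_rel) for lam_rel in np.logspace(-8, 9, 1000)
        )
        assert fit.gcv <= best * (1 + 1e-3)

    def test_fit_is_shift_equivariant(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 80)
        y = np.sin(4 * x) + rng.normal(0, 0.1, 80)
        grid = np.linspace(0, 1, 50)
        f0 = fit_gcv_spline(x, y).predict(grid)
        f5 = fit_gcv_spline(x, y + 5.0).predict(grid)
        assert np.max(np.abs(f5 - f0 - 5.0)) < 1e-8

    def test_edf_monotone_in_penalty(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 100)
        y = rng.normal(0, 1, 100)
        edfs = [spline_edf(x, y, lam) for lam in np.logspace(-6, 8, 10)]
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))

    def test_too_few_distinct_x_rejected(self):
        x = np.repeat(np.arange(5), 4).astype(float)
        with pytest.raises(ValueError):
            fit_gcv_spline(x, np.arange(20.0))


def _gcv_of(x, y, lam_rel):
    from scipy.interpolate import BSpline

    from platypus_popdyn.sensitivity import _penalty_matrix

    ux = np.unique(x)
    t = (x - ux[0]) / (ux[-1] - ux[0])
    n_interior = min(30, len(ux) - 2)
    interior = np.quantile(np.unique(t), np.linspace(0, 1, n_interior + 2)[1:-1])
    interior = np.unique(interior[(interior > 0) & (interior < 1)])
    knots = np.concatenate([[0.0] * 4, interior, [1.0] * 4])
    nb = len(knots) - 4
    B = BSpline.design_matrix(t, knots, 3).toarray()
    BtB = B.T @ B
    omega = _penalty_matrix(knots, nb)
    lam = lam_rel * np.trace(BtB) / np.trace(omega)
    A = np.linalg.inv(BtB + lam * omega)
    fitted = B @ (A @ (B.T @ y))
    rss = float(np.sum((y - fitted) ** 2))
    edf = float(np.trace(A @ BtB))
    return len(y) * rss / (len(y) - edf) ** 2


class TestThresholds:
    def _fit_crossing(self, cross=0.6, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 1, 200)
        y = (x - cross) + rng.normal(0, noise, 200)
        return fit_gcv_spline(x, y)

    def test_constructed_crossing_is_located(self):
        fit = self._fit_crossing()
        rep = threshold_report({"p": fit}, level=0.0)
        assert 0.55 <= rep["p"].threshold <= 0.65
        lo, hi = rep["p"].band
        assert lo <= rep["p"].threshold <= hi

    def test_never_met_reports_none(self):
        fit = self._fit_crossing()
        rep = threshold_report({"p": fit}, level=10.0)
        assert rep["p"].threshold is None

    def test_met_everywhere_reports_range_minimum(self):
        fit = self._fit_crossing()
        rep = threshold_report({"p": fit}, level=-10.0)
        assert rep["p"].threshold == pytest.approx(0.0, abs=1e-9)

    def test_survival_scale_inverts_mortality_axis(self):
        # viability decreasing in mortality: met for mortality <= 0.45, i.e.
        # survival >= 0.55, so the smallest qualifying survival is 0.55
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 200)
        y = (0.45 - x) + rng.normal(0, 0.01, 200)
        fit = fit_gcv_spline(x, y)
        rep = threshold_report({"m": fit}, level=0.0, to_survival={"m"})
        assert rep["m"].threshold == pytest.approx(0.55, abs=0.03)
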