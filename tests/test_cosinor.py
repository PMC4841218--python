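import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from circabench.cosinor import (Cosinor, ModeratedCosinor, acrophase_from_coefs,
                                circular_diff_hours, fit_cosinor,
                                hours_to_hhmm, predict_curve)
from circabench.residualize import ResidualSeries
from circabench.timebase import circular_encode

from .conftest import TWO_PI, make_rhythm
from .oracles import (circular_gap_hours, cosinor_normal_equations,
                      grid_search_cosinor)


def series_of(y, t):
    y = np.asarray(y, float)
    return ResidualSeries(y, np.asarray(t, float), len(y),
                          float(np.sum((y - y.mean()) ** 2)))


class TestFitCosinor:
    def test_noiseless_cosine_recovered_exactly(self):
        t = np.linspace(0, 24, 1000, endpoint=False)
        y = 2.0 * np.cos(TWO_PI * (t - 21.17) / 24.0)
        fit = fit_cosinor(y, t)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase_hours == pytest.approx(21.17, abs=1e-9)
        assert fit.r2_pct == pytest.approx(100.0, abs=1e-6)

    def test_constant_outcome_has_no_rhythm(self):
        t = np.linspace(0, 24, 50, endpoint=False)
        fit = fit_cosinor(np.full(50, 3.7), t)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.r2_pct == 0.0
        assert fit.f_stat == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y, t = make_rhythm(
            n=int(rng.integers(200, 2001)),
            amplitude=rng.uniform(0.2, 2.0),
            acrophase=rng.uniform(0, 24),
            noise_sd=rng.uniform(0.1, 1.0),
            seed=seed + 1000,
            mesor=rng.normal(),
        )
        fit = fit_cosinor(y, t)
        _, _, phi, _ = grid_search_cosinor(y, t)
        m, a, r2 = cosinor_normal_equations(y, t)
        assert circular_gap_hours(fit.acrophase_hours, phi) <= 0.011
        assert fit.mesor == pytest.approx(m, abs=1e-8)
        assert fit.amplitude == pytest.approx(a, abs=1e-8)
        assert fit.r2_pct == pytest.approx(r2, abs=1e-8)

    def test_cross_checked_against_statsmodels(self):
        y, t = make_rhythm(500, 0.8, 9.0, 0.5, seed=42)
        fit = fit_cosinor(y, t)
        s, c = circular_encode(t)
        X = np.column_stack([np.ones_like(s), s, c])
        sm_fit = sm.OLS(y, X).fit()
        assert np.allclose(fit.params, sm_fit.params, atol=1e-10)
        assert fit.r2_pct == pytest.approx(100 * sm_fit.rsquared, abs=1e-8)
        assert fit.f_stat == pytest.approx(float(sm_fit.fvalue), rel=1e-10)
        assert np.allclose(fit.bse, sm_fit.bse, atol=1e-10)

    def test_f_stat_identity_and_two_pass_r2(self):
        y, t = make_rhythm(300, 0.5, 15.0, 0.7, seed=5)
        fit = fit_cosinor(y, t)
        r2 = fit.r2_pct / 100
        assert fit.f_stat == pytest.approx(
            (r2 / 2) / ((1 - r2) / (len(y) - 3)), rel=1e-8
        )
        pred = fit.predict(t)
        sse = np.sum((y - pred) ** 2)
        sst = np.sum((y - np.mean(y)) ** 2)
        assert fit.r2_pct == pytest.approx(100 * (1 - sse / sst), abs=1e-8)

    @given(st.floats(-24, 24))
    @settings(max_examples=30, deadline=None)
    def test_time_shift_equivariance(self, delta):
        y, t = make_rhythm(400, 0.6, 10.0, 0.4, seed=9)
        base = fit_cosinor(y, t)
        shifted = fit_cosinor(y, (t + delta) % 24.0)
        assert circular_gap_hours(
            shifted.acrophase_hours, (base.acrophase_hours + delta) % 24.0
        ) < 1e-6
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-8)
        assert shifted.r2_pct == pytest.approx(base.r2_pct, abs=1e-8)
        assert shifted.f_stat == pytest.approx(base.f_stat, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            Cosinor(np.ones(5), np.arange(5, dtype=float))
        with pytest.raises(ValueError, match="singular|distinct"):
            Cosinor(np.random.default_rng(0).normal(size=20), np.full(20, 7.0))


class TestAcrophaseAlgebra:
    @pytest.mark.parametrize(
        "bs, bc, expected",
        [(0.0, 1.0, 0.0), (1.0, 0.0, 6.0), (-1.0, 0.0, 18.0),
         (0.0, -1.0, 12.0)],
    )
    def test_quadrants(self, bs, bc, expected):
        assert acrophase_from_coefs(bs, bc) == pytest.approx(expected)

    def test_undefined_for_zero_coefs(self):
        with pytest.raises(ValueError, match="undefined"):
            acrophase_from_coefs(0.0, 0.0)

    def test_peak_of_predicted_curve_is_acrophase(self):
        y, t = make_rhythm(500, 1.0, 17.3, 0.2, seed=2)
        fit = fit_cosinor(y, t)
        grid = np.linspace(0, 24, 14400, endpoint=False)
        peak = grid[np.argmax(fit.predict(grid))]
        assert circular_gap_hours(peak, fit.acrophase_hours) < 0.01

    @pytest.mark.parametrize(
        "a, b, expected",
        [(1.0, 23.0, 2.0), (23.0, 1.0, -2.0), (18.0, 6.0, 12.0),
         (0.0, 12.0, 12.0)],
    )
    def test_circular_diff_wraps_into_half_open_band(self, a, b, expected):
        assert circular_diff_hours(a, b) == pytest.approx(expected)

    def test_hhmm_formatting(self):
        assert hours_to_hhmm(21.17) == "21:10"
        assert hours_to_hhmm(0.0) == "00:00"
        assert hours_to_hhmm(23.999) == "00:00"


class TestPredictCurve:
    def test_curve_values(self):
        y, t = make_rhythm(200, 1.0, 0.0, 0.0, seed=1)
        fit = fit_cosinor(y, t)
        assert predict_curve(fit, 0.0) == pytest.approx(1.0, abs=1e-9)
        assert predict_curve(fit, 12.0) == pytest.approx(-1.0, abs=1e-9)
        assert predict_curve(fit, fit.acrophase_hours) == pytest.approx(
            fit.mesor + fit.amplitude, abs=1e-9
        )


class TestModeration:
    def test_constant_moderator_rejected(self):
        y, t = make_rhythm(300, 0.5, 10.0, 0.3, seed=3)
        with pytest.raises(ValueError, match="constant"):
            ModeratedCosinor(y, t, np.ones(300), kind="continuous")
        with pytest.raises(ValueError, match="constant"):
            ModeratedCosinor(y, t, ["only"] * 300, kind="categorical",
                             min_level_n=10)

    def test_small_levels_dropped(self):
        y, t = make_rhythm(300, 0.5, 10.0, 0.3, seed=4)
        mod = np.array(["a"] * 145 + ["b"] * 145 + ["rare"] * 10)
        model = ModeratedCosinor(y, t, mod, min_level_n=100)
        assert model.levels == ["a", "b"]

    def test_joint_f_matches_statsmodels_wald(self):
        rng = np.random.default_rng(6)
        n = 800
        t = rng.uniform(0, 24, n)
        g = rng.integers(0, 2, n)
        y = (0.3 + 0.4 * np.cos(TWO_PI * (t - 20.0 - g) / 24.0)
             + 0.5 * rng.standard_normal(n))
        res = ModeratedCosinor(y, t, np.where(g == 1, "b", "a"),
                               min_level_n=10).fit()
        s, c = circular_encode(t)
        X = np.column_stack([np.ones(n), s, c, g, s * g, c * g])
        sm_fit = sm.OLS(y, X).fit()
        wald = sm_fit.f_test(np.array([[0, 0, 0, 0, 1, 0],
                                       [0, 0, 0, 0, 0, 1]]))
        assert res.joint_f == pytest.approx(float(wald.fvalue), rel=1e-8)
        assert res.p == pytest.approx(float(wald.pvalue), rel=1e-6)
        assert res.df == (2, n - 6)

    def test_categorical_shift_recovered(self):
        # women's rhythm peaks 1.3 h earlier than men's, by construction
        rng = np.random.default_rng(8)
        n = 60_000
        t = rng.uniform(0, 24, n)
        female = rng.random(n) < 0.5
        phase = np.where(female, 20.0 - 1.3, 20.0)
        y = 0.3 * np.cos(TWO_PI * (t - phase) / 24.0) + 0.5 * rng.standard_normal(n)
        res = ModeratedCosinor(
            y, t, np.where(female, "female", "male")
        ).fit()
        assert res.p < 1e-6
        # levels sorted: female first, male second; male - female = +1.3 h
        assert res.acrophase_shift_hours == pytest.approx(1.3, abs=0.25)

    def test_continuous_reference_fits_match_within_group_truth(self):
        rng = np.random.default_rng(10)
        n = 40_000
        t = rng.uniform(0, 24, n)
        m = rng.uniform(0, 1, n)
        phase = 20.0 + 2.0 * m
        y = 0.4 * np.cos(TWO_PI * (t - phase) / 24.0) + 0.3 * rng.standard_normal(n)
        res = ModeratedCosinor(y, t, m, kind="continuous").fit(
            reference_values=[0.0, 1.0]
        )
        # linear-in-coefficients approximation of a 2-h phase ramp
        assert res.acrophase_shift_hours == pytest.approx(2.0, abs=0.35)
        assert res.p < 1e-6

    def test_moderation_from_series(self):
        y, t = make_rhythm(500, 0.5, 10.0, 0.3, seed=12)
        mod = np.random.default_rng(1).choice(["x", "y"], 500)
        from circabench.cosinor import moderation_test
        res = moderation_test(series_of(y, t), mod, min_level_n=50)
        assert set(res.level_fits) == {"x", "y"}
        assert -12.0 < res.acrophase_shift_hours <= 12.0
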