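import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circabench.cosinor import ModeratedCosinor, fit_cosinor
from circabench.simulate import (DEFAULT_TIME_HIST, CircadianSpec, SimConfig,
                                 amplitude_for_target_r2,
                                 cosine_variance_under_density,
                                 sample_times_from_hist, scenario_preset,
                                 simulate)

from .conftest import TWO_PI
from .oracles import circular_gap_hours


class TestConfigValidation:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(race_props={"White": 0.8, "Black": 0.1})
        with pytest.raises(ValueError, match="prop_female"):
            SimConfig(prop_female=1.4)
        with pytest.raises(ValueError, match="target_r2_pct"):
            SimConfig(circadian=CircadianSpec(target_r2_pct=-1))

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="null.*circadian.*selection_only"):
            scenario_preset("bogus")

    def test_presets_encode_stated_magnitudes(self):
        assert scenario_preset("gender_phase_shift").circadian.gender_shift_min == 78.0
        grad = scenario_preset("age_phase_gradient")
        assert grad.circadian.age_shift_min_per_year == 3.0
        assert grad.age_range == (18, 40)
        assert scenario_preset("null").circadian.target_r2_pct == 0.0


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = simulate(scenario_preset("mixed", n=2000, seed=9))
        b = simulate(scenario_preset("mixed", n=2000, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate(scenario_preset("null", n=500, seed=1))
        b = simulate(scenario_preset("null", n=500, seed=2))
        assert not a["d_raw"].equals(b["d_raw"])

    def test_csv_round_trip(self, tmp_path):
        df = simulate(scenario_preset("circadian", n=300, seed=4))
        path = tmp_path / "sim.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path, parse_dates=["timestamp"])
        pd.testing.assert_frame_equal(df.reset_index(drop=True), back)


class TestMarginals:
    @pytest.fixture(scope="class")
    def big(self):
        return simulate(scenario_preset("null", n=100_000, seed=5))

    def test_gender_split(self, big):
        prop = (big["gender"] == "female").mean()
        assert abs(prop - 0.60) < 0.005

    def test_race_proportions(self, big):
        props = big["race"].value_counts(normalize=True)
        assert props["White"] == pytest.approx(0.71, abs=0.01)
        assert props["Black"] == pytest.approx(0.13, abs=0.01)

    def test_age_distribution_matches_mixture(self, big):
        config = scenario_preset("null")
        expected_p = config.age_probabilities()
        ages = np.arange(18, 90)
        observed = big["age"].value_counts().reindex(ages, fill_value=0)
        chi2, p = stats.chisquare(observed, expected_p * len(big))
        assert p > 0.01
        assert (big["age"] <= 40).mean() > 0.75  # young-skewed

    def test_time_distribution_evening_heavy(self, big):
        config = scenario_preset("circadian", n=1, seed=0)
        df = simulate(scenario_preset("null", n=50_000, seed=6),
                      keep_truth=True)
        hours = df["local_hours"]
        evening = ((hours >= 18) & (hours < 23)).mean()
        predawn = ((hours >= 3) & (hours < 8)).mean()
        assert evening > 2 * predawn


class TestAmplitudeCalibration:
    def test_cosine_variance_matches_monte_carlo(self):
        rng = np.random.default_rng(13)
        t = sample_times_from_hist(rng, 400_000, DEFAULT_TIME_HIST)
        c = np.cos(TWO_PI * (t - 21.17) / 24.0)
        v_mc = c.var()
        v = cosine_variance_under_density(DEFAULT_TIME_HIST, 21.17)
        assert v == pytest.approx(v_mc, rel=0.02)

    def test_realized_r2_matches_target(self):
        # population r2 of the injected rhythm tracks the requested value
        config = scenario_preset("gender_phase_shift", n=400_000, seed=14,
                                 circadian=CircadianSpec(
                                     target_r2_pct=4.0, acrophase_hours=21.17))
        df = simulate(config, keep_truth=True)
        resid = df["d_ingroup"] - df.groupby("race")["d_ingroup"].transform("mean")
        fit = fit_cosinor(resid.to_numpy(), df["local_hours"].to_numpy())
        assert fit.r2_pct == pytest.approx(4.0, rel=0.10)

    def test_zero_target_gives_zero_amplitude(self):
        assert amplitude_for_target_r2(0.0, 0.43, DEFAULT_TIME_HIST, 21.0) == 0.0
        with pytest.raises(ValueError):
            amplitude_for_target_r2(100.0, 0.43, DEFAULT_TIME_HIST, 21.0)


class TestScenarioStructure:
    def test_null_p_values_uniform(self):
        # with no rhythm and no selection the cosinor test is calibrated
        pvals = []
        for rep in range(1000):
            df = simulate(scenario_preset("null", n=2000, seed=100_000 + rep),
                          keep_truth=True)
            resid = (df["d_ingroup"]
                     - df.groupby("race")["d_ingroup"].transform("mean"))
            pvals.append(fit_cosinor(resid.to_numpy(),
                                     df["local_hours"].to_numpy()).p)
        _, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_gender_phase_shift_construction(self):
        df = simulate(scenario_preset("gender_phase_shift", n=80_000, seed=15),
                      keep_truth=True)
        resid = (df["d_ingroup"]
                 - df.groupby("race")["d_ingroup"].transform("mean"))
        res = ModeratedCosinor(resid.to_numpy(),
                               df["local_hours"].to_numpy(),
                               df["gender"].to_numpy()).fit()
        # levels sorted [female, male]: men peak later => positive shift
        assert res.acrophase_shift_hours * 60 == pytest.approx(78.0, abs=25.0)
        assert res.p < 1e-4

    def test_dst_phase_shift_sign(self):
        df = simulate(scenario_preset("dst_phase_shift", n=150_000, seed=16),
                      keep_truth=True)
        resid = (df["d_ingroup"]
                 - df.groupby("race")["d_ingroup"].transform("mean"))
        res = ModeratedCosinor(resid.to_numpy(),
                               df["local_hours"].to_numpy(),
                               np.where(df["is_dst"], "dst", "standard")).fit()
        dst_phi = res.level_fits["dst"].acrophase_hours
        std_phi = res.level_fits["standard"].acrophase_hours
        from circabench.cosinor import circular_diff_hours
        assert circular_diff_hours(dst_phi, std_phi) < 0  # earlier during DST

    def test_circadian_acrophase_injected(self):
        df = simulate(scenario_preset("circadian", n=150_000, seed=17),
                      keep_truth=True)
        resid = (df["d_ingroup"]
                 - df.groupby("race")["d_ingroup"].transform("mean"))
        fit = fit_cosinor(resid.to_numpy(), df["local_hours"].to_numpy())
        assert circular_gap_hours(fit.acrophase_hours, 21.17) < 1.0
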