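"""Synthetic-data generators: ground-truth consistency, envelope model,
coupling structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from asymrpe import synth


ALL_COMBOS = [
    ("pRPE", "regular"), ("pRPE", "inverted"),
    ("nRPE", "regular"), ("nRPE", "inverted"),
    ("sRPE", "regular"), ("sRPE", "inverted"),
    ("uRPE", "increasing"), ("uRPE", "decreasing"),
    ("none", "none"),
]


class TestChannelGroundTruth:
    @pytest.mark.parametrize("category,polarity", ALL_COMBOS)
    def test_gain_signs_consistent_with_taxonomy(self, category, polarity, rng):
        for _ in range(20):
            c = synth.make_channel_ground_truth(category, polarity, 0.5, rng)
            if category == "pRPE":
                assert c.g_n == 0 and (c.g_p > 0) == (polarity == "regular")
            elif category == "nRPE":
                # regular nRPE coding = HFA decreases with nRPE magnitude
                assert c.g_p == 0 and (c.g_n < 0) == (polarity == "regular")
            elif category == "sRPE":
                assert c.g_p * c.g_n < 0 and (c.g_p > 0) == (polarity == "regular")
            elif category == "uRPE":
                assert c.g_p * c.g_n > 0 and (c.g_p > 0) == (polarity == "increasing")
            else:
                assert c.g_p == 0 and c.g_n == 0

    def test_invalid_combination_rejected(self, rng):
        with pytest.raises(ValueError):
            synth.make_channel_ground_truth("pRPE", "increasing", 0.5, rng)

    def test_inconsistent_gains_rejected(self, rng):
        c = synth.make_channel_ground_truth("pRPE", "regular", 0.5, rng)
        with pytest.raises(ValueError):
            synth.ChannelGroundTruth(
                subject=c.subject, channel=c.channel, region=c.region, xyz=c.xyz,
                g_ev=0.0, g_p=0.5, g_n=0.5, kernel_peak_s=0.3, kernel_width_s=0.075,
                noise_sd=1.0, ar1=0.5, category="sRPE", polarity="regular",
            )

    def test_region_clouds_are_distinct(self, rng):
        dm = [synth.make_channel_ground_truth("pRPE", "regular", 0.5, rng,
                                              region="dMPFC").xyz for _ in range(30)]
        ins = [synth.make_channel_ground_truth("pRPE", "regular", 0.5, rng,
                                               region="INS").xyz for _ in range(30)]
        assert np.mean([x[0] for x in dm]) > 0 > np.mean([x[0] for x in ins])


class TestEnvelopes:
    time_grid = np.round(np.arange(-0.4, 1.4001, 0.025), 3)

    def rl(self, rng, n=50):
        return pd.DataFrame(
            {"ev": rng.normal(0, 0.5, n),
             "prpe": np.abs(rng.normal(0, 0.5, n)),
             "nrpe": np.abs(rng.normal(0, 0.5, n))}
        )

    def quiet_channel(self, rng, **kw):
        c = synth.make_channel_ground_truth("pRPE", "regular", 1.0, rng,
                                            gain_jitter=0.0, **kw)
        return synth.ChannelGroundTruth(**{**c.__dict__, "noise_sd": 0.0})

    def test_zero_gains_zero_noise_is_identically_zero(self, rng):
        c = synth.make_channel_ground_truth("none", "none", 0.5, rng)
        c = synth.ChannelGroundTruth(**{**c.__dict__, "noise_sd": 0.0})
        env = synth.simulate_hfa_envelopes(c, self.rl(rng), self.time_grid, rng)
        assert np.all(env == 0.0)

    def test_peak_amplitude_is_linear_in_prpe(self, rng):
        c = self.quiet_channel(rng)
        c = synth.ChannelGroundTruth(**{**c.__dict__, "g_ev": 0.0})
        rl = pd.DataFrame({"ev": [0.0], "prpe": [0.5], "nrpe": [0.0]})
        env = synth.simulate_hfa_envelopes(c, rl, self.time_grid, rng)
        k = np.argmin(np.abs(self.time_grid - c.kernel_peak_s))
        assert env[0, k] == pytest.approx(0.5 * c.g_p)
        assert env[0].max() == pytest.approx(0.5 * c.g_p)

    def test_envelope_is_zero_before_feedback(self, rng):
        c = self.quiet_channel(rng)
        env = synth.simulate_hfa_envelopes(c, self.rl(rng), self.time_grid, rng)
        assert np.all(env[:, self.time_grid < 0] == 0.0)

    def test_regression_recovers_gains(self, rng):
        c = synth.make_channel_ground_truth("sRPE", "regular", 0.8, rng,
                                            gain_jitter=0.0)
        rl = self.rl(rng, n=2000)
        env = synth.simulate_hfa_envelopes(c, rl, self.time_grid, rng)
        k = np.argmin(np.abs(self.time_grid - c.kernel_peak_s))
        import statsmodels.api as sm

        X = sm.add_constant(rl[["ev", "prpe", "nrpe"]].to_numpy())
        res = sm.OLS(env[:, k], X).fit()
        assert res.params[1] == pytest.approx(c.g_ev, abs=0.15)
        assert res.params[2] == pytest.approx(c.g_p, rel=0.25)
        assert res.params[3] == pytest.approx(c.g_n, rel=0.25)

    def test_ar1_noise_stationary_sd(self, rng):
        c = synth.make_channel_ground_truth("none", "none", 0.0, rng)
        env = synth.simulate_hfa_envelopes(c, self.rl(rng, 500), self.time_grid, rng)
        assert env.std() == pytest.approx(1.0, abs=0.05)
        lag1 = np.corrcoef(env[:, :-1].ravel(), env[:, 1:].ravel())[0, 1]
        assert lag1 == pytest.approx(0.5, abs=0.05)


class TestRawTrace:
    def test_low_sampling_rate_rejected(self, rng):
        env = np.zeros((2, 10))
        with pytest.raises(ValueError):
            synth.envelope_to_raw_trace(env, np.linspace(0, 1, 10), 200.0, rng)

    def test_band_power_concentrated_in_band(self, rng):
        env = np.zeros((4, 73))
        tgrid = np.round(np.arange(-0.4, 1.4001, 0.025), 3)
        raw, times = synth.envelope_to_raw_trace(env, tgrid, 1000.0, rng,
                                                 pink_sd=0.0, white_sd=0.0)
        from scipy.signal import welch

        f, p = welch(raw, fs=1000.0, nperseg=512, axis=1)
        inband = p[:, (f >= 70) & (f <= 150)].mean()
        outband = p[:, (f >= 200) & (f <= 350)].mean()
        assert inband > 30 * outband


class TestCoupledPair:
    def test_shifted_copy_peaks_at_spec_lag(self, rng):
        from asymrpe import connectivity

        rl = pd.DataFrame({"ev": np.zeros(40), "prpe": np.zeros(40),
                           "nrpe": np.zeros(40)})
        spec = synth.CouplingSpec("S", "i", "d", 75.0, base_gain=0.98,
                                  noise_sd=0.0)
        tg = np.round(np.arange(0, 1.0001, 0.025), 3)
        ins, dm = synth.simulate_coupled_pair(spec, rl, tg, rng)
        r, _ = connectivity.trial_lagged_xcorr(ins, dm)
        lags = connectivity.lag_grid()
        peak_lags = lags[np.nanargmax(r, axis=1)]
        assert np.median(peak_lags) == 75.0

    def test_correlation_increases_with_prpe_modulation(self, rng):
        from asymrpe import connectivity
        from scipy.stats import spearmanr

        n = 300
        rl = pd.DataFrame({"ev": np.zeros(n), "nrpe": np.zeros(n),
                           "prpe": np.abs(rng.normal(0, 0.6, n))})
        spec = synth.CouplingSpec("S", "i", "d", 75.0, base_gain=0.4, m_p=0.4)
        tg = np.round(np.arange(0, 1.0001, 0.025), 3)
        ins, dm = synth.simulate_coupled_pair(spec, rl, tg, rng)
        r, _ = connectivity.trial_lagged_xcorr(ins, dm)
        j = list(connectivity.lag_grid()).index(75.0)
        rho, p = spearmanr(rl["prpe"], r[:, j])
        assert rho > 0.2 and p < 1e-3

    def test_off_grid_lag_rejected(self):
        with pytest.raises(ValueError):
            synth.CouplingSpec("S", "i", "d", 80.0)
        with pytest.raises(ValueError):
            synth.CouplingSpec("S", "i", "d", 425.0)


class TestGenerateCohort:
    def test_same_seed_identical_arrays(self):
        cfg = synth.CohortConfig(n_subjects=2, channels_per_region=2,
                                 couplings_per_subject=1)
        a = synth.generate_cohort(cfg, seed=9)
        b = synth.generate_cohort(cfg, seed=9)
        for key in a.envelopes:
            np.testing.assert_array_equal(a.envelopes[key], b.envelopes[key])
        for key in a.pair_envelopes:
            np.testing.assert_array_equal(a.pair_envelopes[key][1],
                                          b.pair_envelopes[key][1])
        assert a.channel_table.equals(b.channel_table)

    def test_different_seed_differs(self):
        cfg = synth.CohortConfig(n_subjects=1, channels_per_region=1)
        a = synth.generate_cohort(cfg, seed=1)
        b = synth.generate_cohort(cfg, seed=2)
        key = next(iter(a.envelopes))
        assert not np.array_equal(a.envelopes[key], b.envelopes[key])

    def test_category_mix_approximates_configuration(self):
        cfg = synth.CohortConfig(n_subjects=6, channels_per_region=10)
        coh = synth.generate_cohort(cfg, seed=3)
        props = coh.channel_table["category"].value_counts(normalize=True)
        for cat, target in cfg.category_mix.items():
            assert props.get(cat, 0.0) == pytest.approx(target, abs=0.12)

    def test_empty_cohort_is_valid(self):
        cfg = synth.CohortConfig(n_subjects=2, channels_per_region=0)
        coh = synth.generate_cohort(cfg, seed=0)
        assert coh.channels == [] and coh.envelopes == {}
        assert len(coh.trials) == 2

    def test_ground_truth_signs_validated_for_every_channel(self, small_cohort):
        # construction re-checks the category/gain-sign contract
        for c in small_cohort.channels:
            synth._check_gain_signs(c.category, c.g_p, c.g_n)


class TestAdaptiveAgent:
    def test_mean_reversion_slope(self):
        frames = synth.generate_behavior_cohort(
            3, seed=4, agent=synth.AdaptiveAgentConfig(ar_coef=0.25),
            bias_sd=0.0, ar_sd=0.0,
        )
        from asymrpe import behavior

        tab = behavior.rt_adaptation_table(frames)
        import statsmodels.api as sm

        res = sm.OLS(tab["rt_change"],
                     sm.add_constant(tab["prev_rt"])).fit()
        assert res.params["prev_rt"] == pytest.approx(0.25 - 1.0, abs=0.08)

    def test_planted_slowing_appears_in_rts(self):
        slow = synth.generate_behavior_cohort(
            2, seed=5, agent=synth.AdaptiveAgentConfig(prpe_slowing=0.1),
            bias_sd=0.0, ar_sd=0.0,
        )
        for frame in slow.values():
            f = frame.dropna(subset=["rt_s", "gen_prpe"])
            hi = f[f.gen_prpe.shift(1) > 0.8]["rt_s"]
            lo = f[f.gen_prpe.shift(1) == 0.0]["rt_s"]
            assert hi.mean() > lo.mean()
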