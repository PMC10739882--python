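"""Encoding analyses: FDR, classification decision table, category
statistics, spatial gradients, rankit transform."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asymrpe import encoding


class TestFdrCorrect:
    def test_all_ones(self):
        np.testing.assert_allclose(encoding.fdr_correct(np.ones(5)), 1.0)

    def test_hand_computed_step_up(self):
        q = encoding.fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_empty(self):
        assert encoding.fdr_correct(np.array([])).size == 0

    def test_matches_brute_force_step_up(self, rng):
        def brute_force_bh(p):
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            prev = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * n / rank)
                q[i] = prev
            return q

        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(
                encoding.fdr_correct(p), brute_force_bh(p), atol=1e-12
            )

    def test_fdr_control_under_global_null(self, rng):
        rejections = [
            (encoding.fdr_correct(rng.random(23)) < 0.05).mean()
            for _ in range(200)
        ]
        assert np.mean(rejections) <= 0.05


class TestClassifyProfile:
    def test_decision_table_is_exhaustive_and_consistent(self):
        for p_sig, n_sig in itertools.product([False, True], repeat=2):
            for p_peak, n_peak in itertools.product([-0.4, 0.4], repeat=2):
                cat, pol = encoding.classify_profile(p_sig, n_sig, p_peak, n_peak)
                if not p_sig and not n_sig:
                    assert (cat, pol) == ("none", "none")
                elif p_sig and not n_sig:
                    assert cat == "pRPE"
                    assert pol == ("regular" if p_peak > 0 else "inverted")
                elif n_sig and not p_sig:
                    assert cat == "nRPE"
                    assert pol == ("regular" if n_peak < 0 else "inverted")
                elif p_peak * n_peak < 0:
                    assert cat == "sRPE"
                    assert pol == ("regular" if p_peak > 0 else "inverted")
                else:
                    assert cat == "uRPE"
                    assert pol == ("increasing" if p_peak > 0 else "decreasing")

    @pytest.mark.parametrize(
        "p_sig,n_sig,p_peak,n_peak,expected",
        [
            (True, False, 0.5, 0.0, ("pRPE", "regular")),
            (True, True, 0.5, 0.4, ("uRPE", "increasing")),
            (True, True, 0.5, -0.4, ("sRPE", "regular")),
            (False, True, 0.0, 0.3, ("nRPE", "inverted")),
            (False, True, 0.0, -0.3, ("nRPE", "regular")),
        ],
    )
    def test_named_cases(self, p_sig, n_sig, p_peak, n_peak, expected):
        assert encoding.classify_profile(p_sig, n_sig, p_peak, n_peak) == expected


def _series(chan, term, estimates, ps, subject="S0"):
    return pd.DataFrame(
        {"subject": subject, "chan": chan, "term": term,
         "window": np.arange(len(estimates)), "estimate": estimates, "p": ps}
    )


class TestClassifyChannel:
    def test_peak_is_max_abs_among_significant(self):
        est_p = [0.1, -0.9, 0.6, 0.2]
        p_p = [0.2, 0.2, 0.01, 0.01]  # the -0.9 window is NOT significant
        series = pd.concat([
            _series("c", "prpe", est_p, p_p),
            _series("c", "nrpe", [0.0] * 4, [0.9] * 4),
        ])
        cat = encoding.classify_channel(series)
        assert cat.category == "pRPE"
        assert cat.prpe_peak == pytest.approx(0.6)
        assert cat.prpe_peak_window == 2

    def test_none_when_nothing_significant(self):
        series = pd.concat([
            _series("c", "prpe", [0.1, 0.2], [0.6, 0.6]),
            _series("c", "nrpe", [0.1, 0.2], [0.6, 0.6]),
        ])
        assert encoding.classify_channel(series).category == "none"

    def test_classify_units_shares_pair_and_channel_logic(self):
        # same decision table reached through the generic classifier
        series = pd.concat([
            _series("c", "prpe", [0.5, 0.1], [0.001, 0.5]),
            _series("c", "nrpe", [-0.4, -0.1], [0.001, 0.5]),
        ])
        out = encoding.classify_units(series)
        assert out.loc[0, "category"] == "sRPE"
        assert out.loc[0, "polarity"] == "regular"

    def test_own_test_gate_forces_none(self):
        series = pd.concat([
            _series("c", "prpe", [0.5], [0.001]),
            _series("c", "nrpe", [0.0], [0.9]),
        ])
        own = pd.DataFrame(
            {"chan": "c", "term": ["prpe", "nrpe", "joint_rpe"],
             "window": 0, "p": [0.001, 0.9, 0.5]}
        )
        out = encoding.classify_units(series, own)
        assert out.loc[0, "category"] == "none"  # joint gate fails


class TestCategoryProportionStats:
    def make_categories(self, per_subject):
        rows = []
        for subject, spec in per_subject.items():
            for region, cats in spec.items():
                for i, c in enumerate(cats):
                    rows.append({"subject": subject, "region": region,
                                 "category": c, "chan": f"{subject}:{region}{i}"})
        return pd.DataFrame(rows)

    def test_identical_regions_give_p_one(self):
        cats = self.make_categories({
            f"S{i}": {"dMPFC": ["pRPE", "uRPE"], "INS": ["pRPE", "uRPE"]}
            for i in range(5)
        })
        out = encoding.category_proportion_stats(cats)
        assert (out["region_tests"]["p"] == 1.0).all()

    def test_subject_missing_a_region_excluded(self):
        spec = {f"S{i}": {"dMPFC": ["pRPE"], "INS": ["uRPE"]} for i in range(4)}
        spec["S9"] = {"dMPFC": ["pRPE"]}
        out = encoding.category_proportion_stats(self.make_categories(spec))
        assert "S9" not in out["proportions"]["subject"].tolist()

    def test_dominant_category_detected(self):
        rng = np.random.default_rng(0)
        spec = {}
        for i in range(10):
            cats = list(rng.choice(["pRPE"] * 6 + ["nRPE", "sRPE", "uRPE", "uRPE"], 10))
            spec[f"S{i}"] = {"dMPFC": cats, "INS": cats}
        out = encoding.category_proportion_stats(self.make_categories(spec))
        assert out["kruskal"]["p"] < 0.01
        pw = out["pairwise"].set_index(["a", "b"])
        assert pw.loc[("pRPE", "nRPE"), "q"] < 0.05

    def test_all_none_warns_and_skips(self):
        cats = self.make_categories({
            "S0": {"dMPFC": ["none"], "INS": ["none"]},
            "S1": {"dMPFC": ["none"], "INS": ["none"]},
        })
        with pytest.warns(UserWarning):
            out = encoding.category_proportion_stats(cats)
        assert out["kruskal"] is None


class TestSpatialGradientTest:
    def make_xyz(self, rng, categories):
        return pd.DataFrame({
            "category": categories,
            "x": rng.normal(0, 5, len(categories)),
            "y": rng.normal(0, 5, len(categories)),
            "z": rng.normal(0, 5, len(categories)),
        })

    def test_null_coordinates_rarely_significant(self, rng):
        sig = 0
        reps = 30
        for _ in range(reps):
            cats = rng.choice(["pRPE", "uRPE", "nRPE"], 90, p=[0.4, 0.4, 0.2])
            out = encoding.spatial_gradient_test(self.make_xyz(rng, cats))
            coords = out[out["coord"] != "const"]
            sig += (coords["p"] < 0.05).any()
        # with 6+ coordinate tests per run, some runs flag by chance
        assert sig / reps < 0.5

    def test_planted_gradient_recovered(self, rng):
        y = rng.normal(0, 5, 200)
        p_prpe = 1 / (1 + np.exp(-(y / 2)))
        cats = np.where(rng.random(200) < p_prpe, "pRPE", "uRPE")
        frame = pd.DataFrame({"category": cats, "x": rng.normal(0, 5, 200),
                              "y": y, "z": rng.normal(0, 5, 200)})
        out = encoding.spatial_gradient_test(frame)
        row = out[(out.category == "pRPE") & (out.coord == "y")].iloc[0]
        assert row["p"] < 0.01 and row["estimate"] > 0
        assert (out["reference"] == "uRPE").all()

    def test_single_category_returns_none_with_warning(self, rng):
        frame = self.make_xyz(rng, ["pRPE"] * 10)
        with pytest.warns(UserWarning):
            assert encoding.spatial_gradient_test(frame) is None

    def test_sparse_category_dropped(self, rng):
        cats = ["pRPE"] * 40 + ["uRPE"] * 40 + ["sRPE"]
        out = encoding.spatial_gradient_test(self.make_xyz(rng, cats))
        assert "sRPE" not in out["category"].tolist()


class TestRankitTransform:
    def test_single_value_maps_to_zero(self):
        np.testing.assert_allclose(encoding.rankit_transform([3.7]), [0.0])

    def test_empty(self):
        assert encoding.rankit_transform(np.array([])).size == 0

    def test_gaussian_sample_nearly_unchanged(self, rng):
        x = rng.normal(0, 1, 1000)
        y = encoding.rankit_transform(x)
        assert np.corrcoef(x, y)[0, 1] > 0.99

    def test_heavy_tails_normalized(self, rng):
        x = rng.standard_cauchy(500)
        assert stats.shapiro(x).pvalue < 0.01
        assert stats.shapiro(encoding.rankit_transform(x)).pvalue > 0.05

    def test_ties_get_average_rank(self):
        y = encoding.rankit_transform([1.0, 1.0, 2.0])
        assert y[0] == y[1] < y[2]


class TestCompareModelsAic:
    def test_winner_and_deltas(self):
        table = pd.DataFrame({
            "window": [0, 0, 0], "model": ["value", "salience", "asymmetric"],
            "term": "ev", "aic": [110.0, 105.0, 100.0], "p": 0.5,
        })
        res = encoding.WindowModelResults("INS", np.array([0.0]), table)
        out = encoding.compare_models_aic(res)
        assert out.loc[0, "winner"] == "asymmetric"
        assert out.loc[0, "delta_value"] == pytest.approx(10.0)
        assert out.loc[0, "delta_asymmetric"] == 0.0
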