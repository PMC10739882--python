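"""Task simulation: staircase dynamics, outcome labeling, trial rejection,
and the RT-change table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asymrpe import task


CFG = task.TaskConfig()


class TestStaircaseUpdate:
    @pytest.mark.parametrize(
        "condition,tol,outcome,expected",
        [
            ("easy", 100.0, "win", 97.0),     # easy shrinks by 3 on a win
            ("easy", 100.0, "loss", 112.0),   # and grows by 12 on a loss
            ("hard", 20.0, "win", 15.0),      # 20 - 12 = 8, clamped to floor
            ("easy", 195.0, "loss", 200.0),   # 195 + 12 = 207, clamped
            ("hard", 30.0, "loss", 33.0),
            ("easy", 100.0, "neutral", 100.0),
            ("hard", 100.0, "missing", 100.0),
        ],
    )
    def test_update_rules(self, condition, tol, outcome, expected):
        assert task.staircase_update(condition, tol, outcome, CFG) == expected

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            task.staircase_update("easy", 100.0, "draw", CFG)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            CFG.steps("medium")

    @given(
        tol=st.floats(15.0, 200.0),
        outcomes=st.lists(
            st.sampled_from(["win", "loss", "neutral", "missing"]),
            min_size=1, max_size=300,
        ),
        condition=st.sampled_from(["easy", "hard"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_effective_tolerance_never_leaves_bounds(self, tol, outcomes, condition):
        level = tol
        floor, ceiling = CFG.tolerance_bounds
        for outcome in outcomes:
            level = task.staircase_level_update(condition, level, outcome, CFG)
            assert floor <= task.effective_tolerance(level, CFG) <= ceiling


class TestSession:
    def test_reproducible_given_seed(self, agent):
        a = task.run_session(CFG, agent, seed=3)
        b = task.run_session(CFG, agent, seed=3)
        assert a == b
        c = task.run_session(CFG, agent, seed=4)
        assert a != c

    def test_blocks_follow_configured_order(self, session_trials):
        for t in session_trials:
            assert t.condition == CFG.block_order[t.block_index]
        counts = np.bincount([t.block_index for t in session_trials])
        assert (counts == CFG.trials_per_block).all()

    def test_win_labels_match_error_indicator(self, session_trials):
        # brute-force re-check of the win/loss rule on every valenced trial
        for t in session_trials:
            if t.outcome in ("win", "loss"):
                assert (abs(t.error) * 1000.0 <= t.tolerance) == (t.outcome == "win")

    def test_rewards_and_scores(self, session_trials):
        for t in session_trials:
            if t.outcome == "win":
                assert t.reward == 1.0 and t.score_delta == 100
            elif t.outcome == "loss":
                assert t.reward == -1.0 and t.score_delta == -100

    def test_zero_noise_agent_always_wins(self):
        sharp = task.AgentConfig(timing_sd=1e-9)
        trials = task.run_session(CFG, sharp, seed=0)
        assert all(t.outcome == "win" for t in trials)

    def test_fixed_tolerance_win_rate_matches_gaussian_closed_form(self, rng):
        # P(win) = 2*Phi(t/sigma) - 1 for a zero-bias timer at fixed tolerance
        from scipy.stats import norm

        agent = task.AgentConfig(timing_sd=0.06)
        wins = [
            task.simulate_agent_trial(agent, 15.0, 0.0, rng).outcome == "win"
            for _ in range(20000)
        ]
        expected = 2 * norm.cdf(0.25) - 1
        assert np.mean(wins) == pytest.approx(expected, abs=0.01)

    def test_neutral_rate_honored(self, rng):
        agent = task.AgentConfig()
        outs = [
            task.simulate_agent_trial(agent, 100.0, 0.12, rng).outcome
            for _ in range(10000)
        ]
        assert np.mean([o == "neutral" for o in outs]) == pytest.approx(0.12, abs=0.01)

    def test_lapse_yields_missing(self, rng):
        agent = task.AgentConfig(lapse_rate=0.99)
        t = task.simulate_agent_trial(agent, 100.0, 0.0, rng)
        assert t.outcome == "missing" and t.rt is None and np.isnan(t.reward)


class TestRejectTrials:
    def test_range_rules(self):
        def mk(i, rt):
            return task.BehavioralTrial(i, 0, "easy", 100.0, rt, "win", rt - 1 if rt else None)

        trials = [mk(0, 1.0), mk(1, 1.1), mk(2, 0.4), mk(3, 1.6), mk(4, None)]
        kept = task.reject_trials(trials)
        assert [t.trial_index for t in kept] == [0, 1]

    def test_identity_when_all_clean(self, rng):
        trials = [
            task.BehavioralTrial(i, 0, "easy", 100.0, rt, "win", rt - 1)
            for i, rt in enumerate(rng.normal(1.0, 0.03, 50))
        ]
        assert task.reject_trials(trials) == trials

    def test_sd_outlier_removed(self, rng):
        rts = list(rng.normal(1.0, 0.05, 100)) + [1.45]
        trials = [
            task.BehavioralTrial(i, 0, "easy", 100.0, float(rt), "win", float(rt) - 1)
            for i, rt in enumerate(rts)
        ]
        kept = task.reject_trials(trials, sd_mult=3.0)
        assert 100 not in [t.trial_index for t in kept]
        assert len(kept) >= 95

    def test_empty_input(self):
        assert task.reject_trials([]) == []


class TestRtChangeTable:
    def mk(self, i, block, rt, outcome="win"):
        return task.BehavioralTrial(i, block, "easy", 100.0, rt, outcome,
                                    rt - 1 if rt is not None else None)

    def test_single_pair_arithmetic(self):
        tab = task.rt_change_table([self.mk(0, 0, 1.2), self.mk(1, 0, 0.9)])
        assert len(tab) == 1
        assert tab.loc[0, "rt_change"] == pytest.approx(-0.3)
        assert tab.loc[0, "prev_rt"] == pytest.approx(1.2)

    def test_no_row_spans_block_boundary(self):
        tab = task.rt_change_table([self.mk(0, 0, 1.0), self.mk(1, 1, 1.1)])
        assert tab.empty

    def test_missing_breaks_chain(self):
        trials = [self.mk(0, 0, 1.0), self.mk(1, 0, None, "missing"), self.mk(2, 0, 1.2)]
        tab = task.rt_change_table(trials)
        assert tab.empty  # row after the missing trial is dropped too

    def test_rejected_gap_breaks_chain(self):
        # non-consecutive trial_index (a removed trial) yields no row
        tab = task.rt_change_table([self.mk(0, 0, 1.0), self.mk(2, 0, 1.2)])
        assert tab.empty

    def test_row_count_combinatorics(self, session_trials):
        kept = task.reject_trials(session_trials)
        tab = task.rt_change_table(kept)
        n_valid = 0
        for prev, cur in zip(kept, kept[1:]):
            if (cur.block_index == prev.block_index
                    and cur.trial_index == prev.trial_index + 1
                    and prev.rt is not None and cur.rt is not None
                    and prev.outcome != "missing"):
                n_valid += 1
        assert len(tab) == n_valid


class TestStaircaseEquilibrium:
    def test_easy_accuracy_converges_to_twelve_fifteenths(self, agent):
        cfg = task.TaskConfig(block_order=("easy",) * 12, staircase_burnin=300)
        trials = task.run_session(cfg, agent, seed=5)
        acc = np.mean([t.outcome == "win" for t in trials])
        assert acc == pytest.approx(12 / 15, abs=0.03)

    def test_hard_accuracy_converges_to_three_fifteenths(self):
        # wider timing noise keeps the hard equilibrium tolerance interior
        agent = task.AgentConfig(timing_sd=0.10)
        cfg = task.TaskConfig(block_order=("hard",) * 12, staircase_burnin=300)
        trials = task.run_session(cfg, agent, seed=5)
        acc = np.mean([t.outcome == "win" for t in trials])
        assert acc == pytest.approx(3 / 15, abs=0.03)
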