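"""Behavioral regressions: checking policy recovery, RT model, reward rate."""

from __future__ import annotations

import numpy as np
import pytest

from checkdyn.behavior import (
    distance_vs_gauge,
    fit_check_model,
    fit_rt_model,
    reward_rate_profile,
)
from checkdyn.synth import AgentPolicy, TaskConfig, simulate_task

from conftest import make_check_trial, make_work_trial


class TestCheckModel:
    def test_policy_coefficients_recovered(self):
        """Across replicate sessions the gauge slope CI covers the truth in
        most fits and the post-incorrect contrast is unbiased."""
        true = AgentPolicy()
        cover = 0
        inc_est, inc_se = [], []
        n_rep = 8
        for s in range(n_rep):
            trials = simulate_task(TaskConfig(n_blocks=30), true, 100 + s)
            fit = fit_check_model(trials)
            ci = fit.conf_int()
            cover += ci.loc["gauge", 0] < true.beta_gauge < ci.loc["gauge", 1]
            inc_est.append(fit.params["C(prev)[T.INC]"])
            inc_se.append(fit.bse["C(prev)[T.INC]"])
        assert cover >= n_rep - 1
        se_mean = np.mean(inc_se) / np.sqrt(n_rep)
        assert np.mean(inc_est) == pytest.approx(true.beta_prev_incorrect, abs=3 * se_mean)

    def test_post_incorrect_contrast_is_negative(self, default_session_trials):
        """Checking is less likely right after an error (negative INC contrast)."""
        fit = fit_check_model(default_session_trials)
        assert fit.params["C(prev)[T.INC]"] < 0

    def test_gauge_blind_policy_covers_zero(self):
        policy = AgentPolicy(beta0=-2.0, beta_gauge=0.0)
        trials = simulate_task(TaskConfig(n_blocks=25), policy, 21)
        fit = fit_check_model(trials)
        lo, hi = fit.conf_int().loc["gauge"]
        assert lo < 0 < hi

    def test_too_few_checks_raise(self):
        trials = [make_work_trial(i, 10.0 * i) for i in range(30)]
        with pytest.raises(ValueError, match=">=2 checks"):
            fit_check_model(trials)


class TestRtModel:
    def test_difficulty_and_post_error_slowing_recovered(self, default_session_trials):
        policy = AgentPolicy()
        fit, anova = fit_rt_model(default_session_trials)
        # difficulty contrasts on the log scale: mu_d - mu_1
        for level in (2, 3):
            true_delta = (
                policy.rt_mu_by_difficulty[level - 1] - policy.rt_mu_by_difficulty[0]
            )
            lo, hi = fit.conf_int().loc[f"C(difficulty)[T.{level}]"]
            assert lo < true_delta < hi
        lo, hi = fit.conf_int().loc["C(prev)[T.INC]"]
        assert lo < policy.post_error_slowing < hi
        assert fit.params["C(prev)[T.INC]"] > 0
        assert anova.loc["C(difficulty)", "PR(>F)"] < 1e-6

    def test_constant_rts_give_null_coefficients(self):
        rng = np.random.default_rng(0)
        trials = []
        for i in range(60):
            trials.append(
                make_work_trial(
                    i, 10.0 * i,
                    feedback="COR" if rng.random() < 0.7 else "INC",
                    difficulty=int(rng.integers(1, 4)), rt=0.5,
                    block=1 + i // 20,
                )
            )
        fit, _ = fit_rt_model(trials)
        for name, val in fit.params.items():
            if name != "Intercept":
                assert val == pytest.approx(0.0, abs=1e-10)

    def test_non_positive_rt_rejected(self):
        trials = [make_work_trial(i, 10.0 * i, rt=0.5) for i in range(20)]
        trials[5].reaction_time_s = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_rt_model(trials)


class TestRewardRate:
    @staticmethod
    def _toy_block(block: int, t0: float, n_correct: int = 14, with_mid_check: bool = False):
        """A block of back-to-back WORK trials closed by a full-gauge check."""
        trials = []
        t = t0
        i0 = block * 100
        correct = 0
        for j in range(n_correct):
            if with_mid_check and j == 7:
                trials.append(
                    make_check_trial(i0 + len(trials), t, gauge=4, block=block, correct=correct)
                )
                t += 10.0
            trials.append(
                make_work_trial(
                    i0 + len(trials), t, feedback="COR", block=block, correct=correct
                )
            )
            correct += 1
            t += 10.0
        trials.append(
            make_check_trial(i0 + len(trials), t, gauge=7, block=block, correct=correct)
        )
        return trials, t + 10.0

    def test_counterfactual_identity_without_checks(self):
        """Deciles containing no check time have identical observed and
        counterfactual rates (exact)."""
        trials, _ = self._toy_block(1, 0.0, with_mid_check=False)
        prof = reward_rate_profile(trials)
        blk = prof[prof["block"] == 1]
        no_check = blk[blk["check_time_s"] == 0.0]
        assert len(no_check) >= 8
        np.testing.assert_array_equal(
            no_check["rate_with_check"].to_numpy(),
            no_check["rate_without_check"].to_numpy(),
        )

    def test_counterfactual_dominates_where_checks_occur(self):
        trials, t1 = self._toy_block(1, 0.0, with_mid_check=True)
        trials2, _ = self._toy_block(2, t1, with_mid_check=True)
        prof = reward_rate_profile(trials + trials2)
        checked = prof[(prof["check_time_s"] > 0) & (prof["reward_ml"] > 0) & (prof["block"] > 0)]
        assert (checked["rate_without_check"] >= checked["rate_with_check"]).all()
        assert (checked["rate_without_check"] > checked["rate_with_check"]).any()

    def test_toy_block_decile_rates_match_hand_computation(self):
        """Independent arithmetic oracle on a scripted single block."""
        trials, _ = self._toy_block(1, 0.0)
        prof = reward_rate_profile(trials)
        blk = prof[prof["block"] == 1].set_index("decile")
        # block: 14 work trials at t=0,10,...,130 (feedback at t+3.5, reward
        # 0.5 ml each), final check at t=140, EoT at 141.85; bonus 3.5 ml.
        t_total = 141.85
        edges = np.linspace(0.0, t_total, 11)
        fb_times = np.array([10.0 * j + 3.5 for j in range(14)])
        for k in range(10):
            in_bin = np.sum((fb_times >= edges[k]) & (fb_times < edges[k + 1]))
            expected = in_bin * 0.5
            if k == 9:
                expected += 3.5
            assert blk.loc[k + 1, "reward_ml"] == pytest.approx(expected)
            dur_min = (edges[k + 1] - edges[k]) / 60.0
            assert blk.loc[k + 1, "rate_with_check"] == pytest.approx(expected / dur_min)

    def test_incomplete_blocks_are_excluded(self):
        trials, t1 = self._toy_block(1, 0.0)
        dangling = [
            make_work_trial(900 + i, t1 + 10.0 * i, feedback="COR", block=2, correct=i)
            for i in range(5)
        ]
        prof = reward_rate_profile(trials + dangling)
        assert set(prof[prof["block"] > 0]["block"]) == {1}


class TestDistanceVsGauge:
    @staticmethod
    def _block_with_checks(check_positions, gauges, block=1, n=40):
        trials = []
        g_iter = iter(gauges)
        correct = 0
        for i in range(n):
            if i in check_positions:
                trials.append(
                    make_check_trial(block * 100 + i, 10.0 * i, gauge=next(g_iter),
                                     block=block, required=36, correct=correct)
                )
            else:
                trials.append(
                    make_work_trial(block * 100 + i, 10.0 * i, feedback="COR",
                                    block=block, required=36, correct=correct)
                )
                correct = min(correct + 1, 36)
        return trials

    def test_scripted_distances_match_hand_count(self):
        trials = self._block_with_checks({5, 11, 31}, [2, 3, 6])
        res = distance_vs_gauge(trials)
        assert res["pairs"]["distance"].tolist() == [6, 20]
        assert res["pairs"]["gauge_seen"].tolist() == [2, 3]

    def test_gauge_dependent_rechecking_yields_negative_correlation(self):
        # checks get closer together as the seen gauge grows
        positions, gauges = [], []
        pos = 0
        for g, gap in [(1, 12), (2, 10), (3, 8), (4, 6), (5, 4), (6, 2), (7, 1)]:
            positions.append(pos)
            gauges.append(g)
            pos += gap
        trials = self._block_with_checks(set(positions), gauges, n=pos + 2)
        res = distance_vs_gauge(trials)
        assert res["pearson"][0] < -0.8
        assert res["spearman"][0] < -0.8

    def test_metronome_checker_has_no_correlation(self):
        positions = list(range(0, 36, 6))
        gauges = [1, 4, 2, 7, 3, 6]
        trials = self._block_with_checks(set(positions), gauges)
        res = distance_vs_gauge(trials)
        assert abs(res["pearson"][0]) < 1e-9 or np.isnan(res["pearson"][0])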