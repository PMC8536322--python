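"""Statistical battery: bootstrap SE, the three tests against independent
oracles, choking profile, session counts, decomposition, choice preference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact

from rewardreach import (
    ChoiceTrial,
    binomial_proportion_test,
    choice_preference,
    choking_profile,
    condition_stats,
    failure_mode_decomposition,
    mann_whitney,
    session_choking_counts,
    welch_t,
)
from rewardreach.stats import RewardConditionStats, trials_to_frame


def frame_from_labels(cue_labels, outcomes, session="s0", subject="m"):
    return pd.DataFrame({"subject_id": subject, "session_id": session,
                         "trial_index": np.arange(len(outcomes)),
                         "reward_cue": cue_labels, "outcome": outcomes})


def make_stats(cue, n, success_rate, **failure_rates):
    rest = 1.0 - success_rate - sum(failure_rates.values())
    assert rest > -1e-12
    props = {"false_start": 0.0, "delay_drift": 0.0, "undershoot": 0.0,
             "overshoot": 0.0, "target_hold_drift": 0.0, "other": rest}
    props.update(failure_rates)
    return RewardConditionStats(
        cue=cue, n_trials=n, n_success=int(round(n * success_rate)),
        success_rate=success_rate, bootstrap_se=0.0,
        failure_mode_proportions=props)


class TestConditionStats:
    def test_all_success_has_zero_se(self):
        fr = frame_from_labels(["Large"] * 10, ["success"] * 10)
        s = condition_stats(fr, "Large", n_boot=200, seed=0)
        assert s.success_rate == 1.0
        assert s.bootstrap_se == 0.0

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_bootstrap_se_matches_analytic(self, p):
        n = 100
        k = int(round(p * n))
        outcomes = ["success"] * k + ["undershoot"] * (n - k)
        fr = frame_from_labels(["Large"] * n, outcomes)
        s = condition_stats(fr, "Large", n_boot=10_000, seed=1)
        analytic = np.sqrt(p * (1 - p) / n)
        assert s.bootstrap_se == pytest.approx(analytic, rel=0.10)

    def test_seeded_bootstrap_reproducible(self):
        fr = frame_from_labels(["Large"] * 50,
                               ["success"] * 30 + ["overshoot"] * 20)
        a = condition_stats(fr, "Large", n_boot=500, seed=3)
        b = condition_stats(fr, "Large", n_boot=500, seed=3)
        assert a.bootstrap_se == b.bootstrap_se

    def test_missing_cue_raises_with_cues_present(self):
        fr = frame_from_labels(["Small"] * 5, ["success"] * 5)
        with pytest.raises(ValueError, match="Small"):
            condition_stats(fr, "Jackpot")

    def test_proportions_sum_to_one(self):
        fr = frame_from_labels(
            ["Large"] * 6,
            ["success", "undershoot", "overshoot", "false_start",
             "delay_drift", "target_hold_drift"])
        s = condition_stats(fr, "Large", n_boot=0)
        total = s.success_rate + sum(s.failure_mode_proportions.values())
        assert total == pytest.approx(1.0, abs=1e-9)


class TestBinomialProportionTest:
    def test_equal_rates_give_zero_z_unit_p(self):
        r = binomial_proportion_test(30, 60, 45, 90)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_group_swap_symmetry(self):
        a = binomial_proportion_test(90, 100, 70, 100)
        b = binomial_proportion_test(70, 100, 90, 100)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
        assert a.delta_pp == pytest.approx(20.0)

    def test_matches_fisher_within_factor_two(self):
        z = binomial_proportion_test(90, 100, 70, 100)
        _, p_fisher = fisher_exact([[90, 10], [70, 30]])
        assert p_fisher / 2 <= z.p_value <= p_fisher * 2

    def test_matches_permutation_oracle(self):
        # permutation of group membership for (90/100 vs 70/100)
        k1, n1, k2, n2 = 90, 100, 70, 100
        z = binomial_proportion_test(k1, n1, k2, n2)
        pooled = np.concatenate([np.ones(k1 + k2),
                                 np.zeros(n1 + n2 - k1 - k2)])
        rng = np.random.default_rng(2021)
        reps = 100_000
        obs = abs(k1 / n1 - k2 / n2)
        mat = np.tile(pooled, (reps, 1))
        perm = rng.permuted(mat, axis=1)
        diff = np.abs(perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1))
        p_perm = (1 + (diff >= obs - 1e-12).sum()) / (reps + 1)
        mc_se = 3 * np.sqrt(p_perm * (1 - p_perm) / reps) + 2e-4
        assert abs(z.p_value - p_perm) < max(5 * mc_se, 0.5 * p_perm)

    def test_degenerate_all_success_or_failure(self):
        assert binomial_proportion_test(0, 10, 0, 20).p_value == 1.0
        assert binomial_proportion_test(10, 10, 20, 20).p_value == 1.0

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            binomial_proportion_test(0, 0, 1, 2)

    def test_type_one_error_calibrated(self):
        # 2,000 null replicates at n=200 per arm, p=0.5
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 2000
        k1s = rng.binomial(200, 0.5, reps)
        k2s = rng.binomial(200, 0.5, reps)
        for k1, k2 in zip(k1s, k2s):
            if binomial_proportion_test(int(k1), 200, int(k2), 200).p_value \
                    < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestWelchT:
    def test_identical_samples_p_one(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)

    def test_known_effect_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(1.0, 1.0, 100)
        assert welch_t(a, b).p_value < 1e-6

    def test_agrees_with_pooled_t_in_balanced_limit(self):
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 80), rng.normal(0.2, 1, 80)
        w = welch_t(a, b)
        pooled = ttest_ind(a, b, equal_var=True)
        assert w.p_value == pytest.approx(pooled.pvalue, abs=1e-3)

    def test_zero_variance_pair_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0, 1.0], [2.0, 2.0])


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value > 0.9

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=8),
           st.lists(st.integers(0, 5), min_size=1, max_size=8))
    def test_u_statistic_matches_exhaustive_pairwise_count(self, a, b):
        r = mann_whitney(a, b)
        u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert r.statistic == pytest.approx(u_brute)

    def test_p_decreases_under_growing_shift(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 40)
        ps = [mann_whitney(a, a + shift).p_value for shift in (0.0, 1.0, 3.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_medians_reported(self):
        r = mann_whitney([1.0, 2.0, 9.0], [4.0, 5.0, 6.0])
        assert r.extra["median_a"] == 2.0
        assert r.extra["median_b"] == 5.0


class TestChokingProfile:
    def test_all_success_flat_profile(self):
        cues = ["Small", "Medium", "Large", "Jackpot"] * 25
        fr = frame_from_labels(cues, ["success"] * 100)
        prof = choking_profile(fr, n_boot=50, seed=0)
        assert not prof.choking
        assert all(s.success_rate == 1.0 for s in prof.stats.values())
        assert all(c.p_value == 1.0 for c in prof.comparisons)

    def test_strong_jackpot_decrement_flagged(self):
        rng = np.random.default_rng(3)
        cues, outcomes = [], []
        for cue, rate, n in [("Small", 0.65, 800), ("Medium", 0.7, 800),
                             ("Large", 0.75, 800), ("Jackpot", 0.45, 150)]:
            cues += [cue] * n
            outcomes += ["success" if rng.random() < rate else "undershoot"
                         for _ in range(n)]
        prof = choking_profile(frame_from_labels(cues, outcomes), n_boot=0)
        assert prof.choking
        assert prof.comparison("Large", "Jackpot").delta_pp > 0

    def test_missing_cue_error_lists_present(self):
        fr = frame_from_labels(["Small"] * 5, ["success"] * 5)
        with pytest.raises(ValueError, match="Small"):
            choking_profile(fr, n_boot=0)

    def test_extra_pairs_included(self):
        cues = ["Small", "Medium", "Large", "Jackpot", "RareLarge"] * 40
        fr = frame_from_labels(cues, ["success", "undershoot"] * 100)
        prof = choking_profile(
            fr, ordering=("Small", "Medium", "Large", "Jackpot"),
            n_boot=0, extra_pairs=[("Large", "RareLarge")])
        assert prof.comparison("Large", "RareLarge") is not None


class TestSessionCounts:
    def _session(self, sid, large_rate, jackpot_rate, n_large=60,
                 n_jackpot=20):
        cues = ["Large"] * n_large + ["Jackpot"] * n_jackpot
        outs = (["success"] * int(large_rate * n_large) +
                ["undershoot"] * (n_large - int(large_rate * n_large)) +
                ["success"] * int(jackpot_rate * n_jackpot) +
                ["undershoot"] * (n_jackpot - int(jackpot_rate * n_jackpot)))
        return frame_from_labels(cues, outs, session=sid)

    def test_point_decrement_counted(self):
        fr = pd.concat([self._session("s0", 0.7, 0.5),
                        self._session("s1", 0.7, 0.9)], ignore_index=True)
        res = session_choking_counts(fr)
        assert res.counts["m"] == (1, 2)

    def test_tie_not_counted(self):
        fr = self._session("s0", 0.6, 0.6)
        res = session_choking_counts(fr)
        assert res.counts["m"] == (0, 1)

    def test_sessions_missing_cue_excluded(self):
        fr = pd.concat([
            self._session("s0", 0.7, 0.4),
            frame_from_labels(["Large"] * 10, ["success"] * 10, session="s1"),
        ], ignore_index=True)
        res = session_choking_counts(fr)
        assert res.counts["m"] == (1, 1)
        assert ("m", "s1") in res.excluded

    def test_counts_match_brute_force_recount(self):
        from rewardreach import paper_like_params, simulate_labels
        params = paper_like_params()
        frames = []
        for sid in range(12):
            cues, labels = simulate_labels(params, 400, seed=3000 + sid)
            frames.append(frame_from_labels(cues, labels,
                                            session=f"s{sid:02d}"))
        fr = pd.concat(frames, ignore_index=True)
        res = session_choking_counts(fr)
        # independent recount with plain loops
        expected = 0
        for sid in sorted(fr["session_id"].unique()):
            sub = fr[fr["session_id"] == sid]
            rl = np.mean(sub[sub.reward_cue == "Large"].outcome == "success")
            rj = np.mean(sub[sub.reward_cue == "Jackpot"].outcome == "success")
            expected += rl > rj
        assert res.counts["m"][0] == expected
        assert res.counts["m"][1] == 12


class TestDecomposition:
    def test_identical_conditions_contribute_zero(self):
        a = make_stats("Large", 100, 0.7, undershoot=0.2, overshoot=0.1)
        contrib = failure_mode_decomposition(a, a)
        assert all(v == 0.0 for v in contrib.values())

    def test_pure_undershoot_shift_conserved(self):
        a = make_stats("Large", 100, 0.7, undershoot=0.2, overshoot=0.1)
        b = make_stats("Jackpot", 100, 0.6, undershoot=0.3, overshoot=0.1)
        contrib = failure_mode_decomposition(a, b)
        assert contrib["undershoot"] == pytest.approx(10.0)
        delta_success = (b.success_rate - a.success_rate) * 100
        assert sum(contrib.values()) == pytest.approx(-delta_success,
                                                      abs=1e-9)

    def test_conservation_on_synthetic_profile(self):
        from rewardreach import paper_like_params, simulate_labels
        cues, labels = simulate_labels(paper_like_params(), 3000, seed=17)
        prof = choking_profile(frame_from_labels(cues, labels), n_boot=0)
        a, b = prof.stats["Large"], prof.stats["Jackpot"]
        contrib = failure_mode_decomposition(a, b)
        delta = (b.success_rate - a.success_rate) * 100
        assert sum(contrib.values()) == pytest.approx(-delta, abs=1e-9)
        # undershoot dominates the Jackpot decrement by construction
        assert contrib["undershoot"] == max(contrib.values())


class TestChoicePreference:
    def test_always_larger_gives_unit_preference(self):
        mags = {"Small": 0.1, "Jackpot": 2.0}
        trials = [ChoiceTrial("m", "Small", "Jackpot", "right")] * 10
        pref = choice_preference(trials, mags)
        assert pref.loc[0, "preference"] == 1.0

    def test_equal_cue_split_has_half_side_bias(self):
        mags = {"Large": 0.3}
        trials = ([ChoiceTrial("m", "Large", "Large", "left")] * 5 +
                  [ChoiceTrial("m", "Large", "Large", "right")] * 5)
        pref = choice_preference(trials, mags)
        assert pref.loc[0, "side_bias"] == 0.5

    def test_nineteen_of_twenty(self):
        mags = {"Medium": 0.2, "Large": 0.3}
        trials = ([ChoiceTrial("m", "Medium", "Large", "right")] * 19 +
                  [ChoiceTrial("m", "Medium", "Large", "left")])
        pref = choice_preference(trials, mags)
        assert pref.loc[0, "preference"] == pytest.approx(0.95)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choice_preference([], {})


def test_trials_to_frame_uses_truth_labels():
    from rewardreach import generate_session, paper_like_params
    session = generate_session(paper_like_params(), 20, seed=4)
    fr = trials_to_frame(session)
    assert list(fr["outcome"]) == [s.truth.label for s in session]
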