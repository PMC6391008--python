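"""Recovery, reliability, temporal stability, sweep and power machinery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from twostage.psychometrics import (PowerConfig,
                                    RecoveryConfig, manova_chi2,
                                    parameter_recovery, power_analysis,
                                    reliability_curve, simulate_cohort,
                                    spearman_brown, split_half,
                                    temporal_stability, w_sweep)
from twostage.scores import mb1_choice


class TestSpearmanBrown:
    def test_known_values(self):
        assert spearman_brown(0.5) == pytest.approx(2 / 3)
        assert spearman_brown(1.0) == 1.0
        assert spearman_brown(0.0) == 0.0

    @given(st.floats(0.0, 0.999), st.floats(0.0, 0.999))
    def test_monotone(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert spearman_brown(lo) <= spearman_brown(hi)


class TestSplitHalf:
    def test_identical_halves_give_unit_reliability(self, ddm_cohort):
        seen = {}

        def stable_score(sess, mask=None):
            return seen.setdefault(sess.subject_id,
                                   float(len(seen)))  # same in both halves

        rep = split_half(ddm_cohort[:10], stable_score)
        assert rep.r_raw == pytest.approx(1.0)
        assert rep.r_corrected == pytest.approx(1.0)

    def test_independent_noise_halves_near_zero(self, ddm_cohort):
        rng = np.random.default_rng(0)

        def noise_score(sess, mask=None):
            return float(rng.standard_normal())

        rs = [split_half(ddm_cohort, noise_score).r_raw for _ in range(40)]
        assert abs(np.mean(rs)) < 0.1

    def test_undefined_half_scores_dropped_and_counted(self, ddm_cohort):
        def sometimes_nan(sess, mask=None):
            if sess.subject_id.endswith("0"):
                return float("nan")
            return float(hash(sess.subject_id) % 97) + (
                0.01 * float(np.mean(mask)))

        rep = split_half(ddm_cohort[:10], sometimes_nan)
        assert rep.n_dropped == 1
        assert rep.n_subjects == 9

    def test_too_few_subjects_raise(self, ddm_cohort):
        with pytest.raises(ValueError):
            split_half(ddm_cohort[:2], mb1_choice)

    def test_conditioning_trial_kept_regardless_of_parity(self, ddm_cohort):
        """Both halves see roughly half the stay pairs each (the previous
        trial's coding is retained, only the outcome trial is split)."""
        from twostage.scores import stay_table
        s = ddm_cohort[0]
        odd = (s.trials["trial"].to_numpy() % 2) == 1
        n_odd = stay_table(s, odd).counts.sum()
        n_even = stay_table(s, ~odd).counts.sum()
        n_all = stay_table(s).counts.sum()
        assert n_odd + n_even == n_all
        assert abs(int(n_odd) - int(n_even)) <= 2


class TestReliabilityCurve:
    def test_full_length_grid_point_equals_split_half(self, ddm_cohort):
        n = ddm_cohort[0].n_trials
        curve = reliability_curve(ddm_cohort, mb1_choice, [n])
        rep = split_half(ddm_cohort, mb1_choice)
        assert curve["r_corrected"].iloc[0] == pytest.approx(rep.r_corrected)

    def test_grid_outside_sessions_rejected(self, ddm_cohort):
        with pytest.raises(ValueError):
            reliability_curve(ddm_cohort, mb1_choice, [10_000])

    def test_curve_increases_in_expectation(self):
        sessions = simulate_cohort("ddm11", 80, 300, seed=60)
        curve = reliability_curve(sessions, mb1_choice, [60, 150, 300])
        r = curve["r_corrected"].to_numpy()
        assert r[2] > r[0]


class TestTemporalStability:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        res = temporal_stability(x, x)
        assert res.r == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        res = temporal_stability(np.ones(8), np.arange(8.0))
        assert not res.defined and np.isnan(res.r)

    def test_partial_correlation_matches_rank_residual_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=40)
        x = 0.8 * z + rng.normal(size=40)
        y = 0.5 * z + rng.normal(size=40)
        res = temporal_stability(x, y, method="partial", covariate=z)
        from scipy.stats import pearsonr, rankdata
        rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
        resid = lambda a, b: a - np.polyval(np.polyfit(b, a, 1), b)
        oracle = pearsonr(resid(rx, rz), resid(ry, rz)).statistic
        assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_spearman_option(self):
        x = [1.0, 2.0, 3.0, 4.0, 50.0]
        y = [2.0, 3.0, 4.0, 5.0, 6.0]
        assert temporal_stability(x, y, "spearman").r == pytest.approx(1.0)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            temporal_stability([1.0, 2.0], [1.0, 2.0])


class TestManova:
    def test_df_is_number_of_scores(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(20, 2)), rng.normal(size=(20, 2))
        _, df, _ = manova_chi2(a, b)
        assert df == 2

    def test_identical_groups_give_zero_statistic(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 2))
        chi2, _, p = manova_chi2(a, a.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_wilks_lambda_matches_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(4)
        a = rng.normal(size=(25, 2))
        b = rng.normal(loc=0.5, size=(30, 2))
        chi2, df, _ = manova_chi2(a, b)
        y = np.vstack([a, b])
        g = np.r_[np.zeros(25), np.ones(30)]
        mv = MANOVA(y, np.column_stack([np.ones(55), g]))
        wilks = mv.mv_test().results["x1"]["stat"].loc["Wilks' lambda",
                                                      "Value"]
        n = 55
        expected = -(n - 1 - (2 + 2) / 2) * np.log(wilks)
        assert chi2 == pytest.approx(expected, rel=1e-8)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            manova_chi2(np.zeros((2, 2)), np.zeros((5, 2)))


class TestPower:
    def test_separated_groups_reach_full_power(self):
        cfg = PowerConfig(effect_size="large", n_per_group=15, n_trials=150,
                          n_iterations=15, w_sd=0.02, seed=5)
        # stretch the separation far beyond the nominal large effect
        cfg.EFFECTS = dict(cfg.EFFECTS, large=(0.05, 0.95))
        res = power_analysis(cfg)
        assert res.power > 0.9

    def test_null_effect_matches_alpha(self):
        res = power_analysis(PowerConfig(effect_size="null", n_per_group=25,
                                         n_trials=100, n_iterations=250,
                                         seed=6))
        assert abs(res.power - 0.05) < 0.04

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PowerConfig(effect_size="tiny")
        with pytest.raises(ValueError):
            PowerConfig(w_sd=0.0)


class TestWSweep:
    @pytest.fixture(scope="class")
    def sweep(self):
        return w_sweep(w_grid=[0.0, 0.5, 1.0], n_experiments=6,
                       n_trials=1500, seed=7)

    def test_best_state_has_larger_spread(self, sweep):
        assert sweep.dq_best_mean > sweep.dq_worst_mean

    def test_model_based_agents_reach_best_state_via_common(self, sweep):
        p = sweep.per_w["p_best_via_common"].to_numpy()
        assert p[-1] > p[0]

    def test_scores_increase_with_w(self, sweep):
        assert sweep.per_w["mb1_mean"].iloc[-1] > sweep.per_w["mb1_mean"].iloc[0]
        assert sweep.per_w["mb2_mean"].iloc[-1] > sweep.per_w["mb2_mean"].iloc[0]


class TestRecoverySmoke:
    def test_refit_ranks_agents_and_counts_failures(self):
        cfg = RecoveryConfig(model="rl7", n_agents=8, n_trials=150, seed=8)
        from twostage.fitting import FitOptions
        cfg.fit_options = FitOptions(seed=8, popsize=6, max_generations=30)
        res = parameter_recovery(cfg)
        assert set(res.correlations) == {"alpha1", "alpha2", "beta1", "beta2",
                                        "lam", "w", "p"}
        assert res.n_failures == 0
        assert res.correlations["w"] > 0  # even a tiny run ranks w positively
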