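"""Model-agnostic scores: stay tables, MB-I/MB-II, mixed models, eta^2."""

import warnings

import numpy as np
import pytest

from conftest import make_session
from twostage import DDMRLParams, TaskConfig, simulate_agent
from twostage.scores import (eta_squared, hierarchical_scores, mb1_choice,
                             mb2_rt, score_table, stay_table)


def _repeat_session(choice1, transition, reward, **kw):
    n = len(choice1)
    return make_session(choice1, transition, [1] * n, reward, **kw)


class TestStayTable:
    def test_always_stay_agent_has_unit_cells(self):
        rng = np.random.default_rng(0)
        n = 400
        trans = list(np.where(rng.random(n) < 0.7, "common", "rare"))
        sess = _repeat_session([1] * n, trans, list(rng.integers(0, 2, n)))
        t = stay_table(sess)
        assert np.allclose(t.probs, 1.0)

    def test_alternating_agent_has_zero_cells(self):
        rng = np.random.default_rng(1)
        n = 400
        trans = list(np.where(rng.random(n) < 0.7, "common", "rare"))
        sess = _repeat_session([1, 2] * (n // 2), trans,
                               list(rng.integers(0, 2, n)))
        assert np.allclose(stay_table(sess).probs, 0.0)

    def test_hand_counted_eight_trial_session(self):
        # conditioning cells (transition, reward) of trials 1..7; stay is
        # whether choice1 repeats on the following trial
        sess = _repeat_session(
            choice1=[1, 1, 2, 2, 1, 1, 1, 2],
            transition=["common", "rare", "common", "common",
                        "rare", "common", "rare", "common"],
            reward=[1, 1, 0, 1, 0, 1, 0, 1])
        t = stay_table(sess)
        # (common, rew): trials 1, 4, 6 -> stays 1, 0, 1
        assert t.cell("common", 1) == pytest.approx(2 / 3)
        # (common, unrew): trial 3 -> stay 1
        assert t.cell("common", 0) == 1.0
        # (rare, rew): trial 2 -> stay 0
        assert t.cell("rare", 1) == 0.0
        # (rare, unrew): trials 5, 7 -> stays 1, 0
        assert t.cell("rare", 0) == pytest.approx(1 / 2)
        assert t.counts.tolist() == [3, 1, 1, 2]

    def test_pairs_spanning_block_break_are_dropped(self):
        sess = _repeat_session([1, 1, 1, 1], ["common"] * 4, [1, 1, 1, 1],
                               block=[1, 1, 2, 2])
        assert stay_table(sess).counts.sum() == 2  # pairs (1,2) and (3,4)

    def test_empty_cell_marks_score_undefined(self):
        sess = _repeat_session([1, 1, 1], ["common"] * 3, [1, 1, 1])
        assert np.isnan(mb1_choice(sess))


class TestMB1:
    def test_pure_model_based_extreme(self):
        # cells (cr, rr, cu, ru) = (1, 0, 0, 1) -> score 2
        probs = {("common", 1): 1.0, ("rare", 1): 0.0,
                 ("common", 0): 0.0, ("rare", 0): 1.0}
        score = (probs["common", 1] - probs["rare", 1]) \
            - (probs["common", 0] - probs["rare", 0])
        assert score == 2.0

    def test_reward_main_effect_only_scores_zero(self):
        assert (0.8 - 0.8) - (0.3 - 0.3) == 0.0

    def test_interaction_arithmetic_on_constructed_session(self):
        # build a long deterministic session realising target cell
        # probabilities (.8, .6, .4, .7) for (cr, rr, cu, ru)
        rng = np.random.default_rng(2)
        cells = {("common", 1): 0.8, ("rare", 1): 0.6,
                 ("common", 0): 0.4, ("rare", 0): 0.7}
        c1, trans, rew = [1], [], []
        n = 4000
        for t in range(n - 1):
            tr = "common" if rng.random() < 0.7 else "rare"
            r = int(rng.random() < 0.5)
            trans.append(tr)
            rew.append(r)
            stay = rng.random() < cells[tr, r]
            c1.append(c1[-1] if stay else 3 - c1[-1])
        trans.append("common")
        rew.append(1)
        sess = _repeat_session(c1, trans, rew)
        assert mb1_choice(sess) == pytest.approx(
            (0.8 - 0.6) - (0.4 - 0.7), abs=0.08)


class TestMB2:
    def test_rt_difference_arithmetic(self):
        trans = ["common", "rare"] * 10
        rt2 = [0.7, 0.9] * 10
        sess = make_session([1] * 20, trans, [1] * 20, [1] * 20,
                            rt1=[0.5] * 20, rt2=rt2)
        assert mb2_rt(sess) == pytest.approx(0.2)

    def test_single_transition_type_undefined(self):
        sess = make_session([1] * 5, ["common"] * 5, [1] * 5, [1] * 5,
                            rt1=[0.5] * 5, rt2=[0.6] * 5)
        assert np.isnan(mb2_rt(sess))

    def test_mb2_increases_with_model_based_weight(self):
        means = []
        for w in (0.0, 0.5, 1.0):
            vals = []
            for rep in range(6):
                p = DDMRLParams(alpha1=0.6, alpha2=0.6, lam=0.5, w=w, p=0.1,
                                b1=4.0, a1=1.5, tau1=0.2, b2=4.0, a2=1.5,
                                tau2=0.2)
                sess = simulate_agent(p, TaskConfig(n_trials=2000),
                                      seed=700 + rep + int(10 * w))
                vals.append(mb2_rt(sess))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_rt_rescaling_scales_score(self, ddm_session):
        from twostage.task import SessionData
        base = mb2_rt(ddm_session)
        t = ddm_session.trials.copy()
        t[["rt1", "rt2"]] *= 1000.0
        scaled = SessionData("s", "t1", ddm_session.config, t)
        assert mb2_rt(scaled) == pytest.approx(1000.0 * base)


class TestHierarchicalScores:
    def test_identical_subjects_shrink_to_fixed_effect(self):
        p = DDMRLParams(0.6, 0.6, 0.5, 0.8, 0.1, 4.0, 1.5, 0.3, 4.0, 1.5, 0.3)
        cfg = TaskConfig(n_trials=150)
        sessions = [simulate_agent(p, cfg, 40 + i, f"s{i}") for i in range(8)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = hierarchical_scores(sessions)
        mb2 = h["mb2_hierarchical"].to_numpy()
        assert mb2.std() < np.std([mb2_rt(s) for s in sessions])
        assert np.all(np.isfinite(mb2))

    def test_flipping_transition_coding_flips_mb2_sign(self, ddm_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plus = hierarchical_scores(ddm_cohort, transition_sign=1.0)
            minus = hierarchical_scores(ddm_cohort, transition_sign=-1.0)
        # antisymmetric up to the mixed-model convergence tolerance
        assert np.allclose(plus["mb2_hierarchical"],
                           -minus["mb2_hierarchical"], atol=1e-4)

    def test_rank_agreement_with_individual_scores(self, ddm_cohort):
        from scipy.stats import spearmanr
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = hierarchical_scores(ddm_cohort)
        r1 = spearmanr(h["mb1_hierarchical"],
                       [mb1_choice(s) for s in ddm_cohort]).statistic
        r2 = spearmanr(h["mb2_hierarchical"],
                       [mb2_rt(s) for s in ddm_cohort]).statistic
        assert r1 > 0 and r2 > 0

    def test_score_table_shapes(self, ddm_cohort):
        df = score_table(ddm_cohort[:5])
        assert len(df) == 5
        assert {"mb1_individual", "mb2_individual",
                "p_stay_common_rew", "n_rare_unrew"} <= set(df.columns)


class TestEtaSquared:
    def test_no_effect_is_near_zero(self):
        rng = np.random.default_rng(3)
        sessions = []
        for i in range(30):
            n = 200
            trans = list(np.where(rng.random(n) < 0.7, "common", "rare"))
            rt2 = rng.normal(0.8, 0.05, n)  # same law in both conditions
            sessions.append(make_session(
                list(rng.integers(1, 3, n)), trans,
                list(rng.integers(1, 3, n)), list(rng.integers(0, 2, n)),
                rt1=[0.5] * n, rt2=rt2, subject_id=f"s{i}"))
        assert eta_squared(sessions, "mb2") < 0.05

    def test_deterministic_effect_is_one(self):
        sessions = []
        for i in range(10):
            trans = ["common", "rare"] * 50
            rt2 = [0.6 if tr == "common" else 0.9 for tr in trans]
            sessions.append(make_session([1] * 100, trans, [1] * 100,
                                         [1] * 100, rt1=[0.5] * 100, rt2=rt2,
                                         subject_id=f"s{i}"))
        assert eta_squared(sessions, "mb2") == pytest.approx(1.0)

    def test_hand_computed_two_condition_table(self):
        # two subjects, cell means chosen so SS can be done by hand:
        # common: .6, .8 / rare: 1.0, 1.2 -> grand mean .9
        # SS_total = .09+.01+.01+.09 = .2 ; SS_transition = 4*(.2)^2/... :
        # condition means .7 and 1.1 -> SS_effect = 2*(.2^2)*2 = .16
        sessions = []
        for i, (rc, rr) in enumerate([(0.6, 1.0), (0.8, 1.2)]):
            trans = ["common", "rare"] * 50
            rt2 = [rc if tr == "common" else rr for tr in trans]
            sessions.append(make_session([1] * 100, trans, [1] * 100,
                                         [1] * 100, rt1=[0.5] * 100, rt2=rt2,
                                         subject_id=f"s{i}"))
        assert eta_squared(sessions, "mb2") == pytest.approx(0.16 / 0.2)

    def test_degenerate_variance_undefined(self):
        trans = ["common", "rare"] * 20
        sess = make_session([1] * 40, trans, [1] * 40, [1] * 40,
                            rt1=[0.5] * 40, rt2=[0.7] * 40)
        assert np.isnan(eta_squared([sess], "mb2"))


def test_scores_invariant_to_subject_ordering(ddm_cohort):
    fwd = score_table(ddm_cohort[:6])
    rev = score_table(ddm_cohort[:6][::-1])
    merged = fwd.merge(rev, on="subject_id", suffixes=("_f", "_r"))
    assert np.allclose(merged["mb1_individual_f"],
                       merged["mb1_individual_r"], equal_nan=True)
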