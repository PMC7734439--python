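"""Exclusion rules, behavioral summaries, SDT statistics, and group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blindbet import analysis, observer, synth


def make_record(**overrides):
    base = {
        "subject_id": "s", "trial_index": 0, "is_practice": False,
        "ep_interval": 1, "true_emotion": "fearful", "intensity_pct": 25.0,
        "face_set_1": 1, "face_set_2": 2,
        "resp_emotion_1": "fearful", "resp_emotion_2": "happy", "resp_bet": 1,
        "rt_emotion_1_ms": 1200.0, "rt_emotion_2_ms": 1200.0, "rt_bet_ms": 1200.0,
    }
    base.update(overrides)
    return base


class TestTrialValidity:
    def test_fully_valid_trial(self):
        v = analysis.classify_trial(make_record())
        assert v.valid_for_bet and v.valid_for_correct

    def test_slow_ea_response_only_spoils_bet_mask(self):
        # EP is interval 1, so a slow interval-2 (EA) emotion response
        # invalidates the bet analysis but not the accuracy analysis
        v = analysis.classify_trial(make_record(rt_emotion_2_ms=5000.0))
        assert not v.valid_for_bet and v.valid_for_correct

    def test_missing_bet_spoils_both(self):
        v = analysis.classify_trial(make_record(resp_bet=None, rt_bet_ms=None))
        assert not v.valid_for_bet and not v.valid_for_correct

    def test_slow_ep_response_spoils_both(self):
        v = analysis.classify_trial(make_record(rt_emotion_1_ms=4001.0))
        assert not v.valid_for_bet and not v.valid_for_correct

    def test_threshold_is_inclusive(self):
        v = analysis.classify_trial(make_record(rt_emotion_1_ms=4000.0))
        assert v.valid_for_bet and v.valid_for_correct

    def test_bet_mask_implies_correct_mask(self, cohort_records):
        v = analysis.add_validity(cohort_records)
        assert (~v["valid_for_bet"] | v["valid_for_correct"]).all()


class TestFilterSubjects:
    @staticmethod
    def _dataset(n_invalid):
        rows = []
        for i in range(112):
            r = make_record(trial_index=i)
            if i < n_invalid:
                r["resp_bet"] = None
                r["rt_bet_ms"] = None
            rows.append(r)
        return pd.DataFrame(rows)

    def test_fully_valid_subject_retained(self):
        retained, excluded = analysis.filter_subjects({"a": self._dataset(0)})
        assert "a" in retained and not excluded

    def test_just_below_threshold_excluded(self):
        # 89/112 = 79.5% valid -> excluded
        retained, excluded = analysis.filter_subjects({"a": self._dataset(23)})
        assert "a" in excluded

    def test_just_above_threshold_retained(self):
        # 90/112 = 80.4% valid -> retained ("fewer than 80%" is strict)
        retained, excluded = analysis.filter_subjects({"a": self._dataset(22)})
        assert "a" in retained


class TestSummaries:
    def test_perfect_subject(self):
        df = pd.DataFrame([make_record(trial_index=i, intensity_pct=lvl)
                           for i, lvl in enumerate([5.0] * 4 + [75.0] * 4)])
        s = analysis.summarize_subject(df)
        assert (s.table["pct_correct"] == 1.0).all()
        assert (s.table["pct_bet_ep"] == 1.0).all()

    def test_zero_valid_trials_flagged_not_zero(self):
        rows = [make_record(trial_index=0, intensity_pct=5.0),
                make_record(trial_index=1, intensity_pct=75.0,
                            resp_bet=None, rt_bet_ms=None)]
        s = analysis.summarize_subject(pd.DataFrame(rows))
        assert np.isnan(s.table.loc[75.0, "pct_correct"])
        assert s.table.loc[75.0, "n_valid_correct"] == 0

    def test_cohort_summaries_rise_with_intensity(self, cohort_records):
        datasets = synth.records_by_subject(cohort_records)
        summaries = {sid: analysis.summarize_subject(df) for sid, df in datasets.items()}
        pc = analysis.group_level_matrix(summaries, "pct_correct").mean(axis=0)
        pb = analysis.group_level_matrix(summaries, "pct_bet_ep").mean(axis=0)
        assert (pc.diff().dropna() > 0).all()
        assert (pb.diff().dropna() > 0).all()
        # calibrated cohort spans roughly chance to 0.9
        assert 0.45 < pc.iloc[0] < 0.62 and 0.8 < pc.iloc[-1] < 0.97


class TestSDT:
    def test_boundary_corrections(self):
        assert analysis.corrected_rates(0, 32, 5, 32)[0] == pytest.approx(1 / 33)
        assert analysis.corrected_rates(32, 32, 5, 32)[0] == pytest.approx(32 / 33)
        assert analysis.corrected_rates(16, 32, 0, 16) == (
            pytest.approx(0.5), pytest.approx(1 / 17))

    def test_interior_rates_unchanged(self):
        hr, far = analysis.corrected_rates(16, 32, 8, 32)
        assert (hr, far) == (0.5, 0.25)

    def test_rejects_impossible_counts(self):
        with pytest.raises(ValueError):
            analysis.corrected_rates(33, 32, 0, 32)
        with pytest.raises(ValueError):
            analysis.corrected_rates(1, 0, 0, 32)

    def test_dprime_zero_at_equal_rates(self):
        d, c = analysis.sdt_stats(0.5, 0.5)
        assert d == 0.0 and c == 0.0

    def test_symmetric_rates(self):
        d, c = analysis.sdt_stats(0.8, 0.2)
        assert d == pytest.approx(2 * stats.norm.ppf(0.8))
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_criterion_sign_convention(self):
        # hr + far > 1 means liberal toward the signal ("fearful") response
        _, c = analysis.sdt_stats(0.69, 0.31 + 0.1)
        assert c < 0

    def test_antisymmetry_properties(self, rng):
        for _ in range(50):
            hr, far = rng.uniform(0.05, 0.95, 2)
            d1, c1 = analysis.sdt_stats(hr, far)
            d2, _ = analysis.sdt_stats(far, hr)
            _, c2 = analysis.sdt_stats(1 - far, 1 - hr)
            assert d1 == pytest.approx(-d2)
            assert c1 == pytest.approx(-c2)

    def test_boundary_rates_rejected(self):
        with pytest.raises(ValueError):
            analysis.sdt_stats(1.0, 0.2)

    def test_saturated_subject_hits_corrected_ceiling(self):
        """All-correct data gives d' = 2 z(n/(n+1)) exactly after correction."""
        df = pd.DataFrame([
            make_record(trial_index=i, true_emotion=em,
                        resp_emotion_1=em, intensity_pct=25.0)
            for i, em in enumerate(["fearful"] * 16 + ["happy"] * 16)
        ])
        t = analysis.subject_sdt_by_level(df)
        assert t.loc[25.0, "d_prime"] == pytest.approx(2 * stats.norm.ppf(16 / 17))


class TestFearBias:
    def test_unbiased_cohorts_nominal_type_I_error(self, session_spec):
        """With a symmetric observer the per-level criterion tests reject at
        roughly the nominal familywise rate (binomial tolerance)."""
        cfg = observer.ObserverConfig(seed=31)
        n_cohorts, alpha = 150, 0.05
        any_sig = 0
        for c in range(n_cohorts):
            recs = synth.simulate_cohort(
                synth.default_cohort(10, seed=50_000 + c, p_miss=0.0),
                session_spec, cfg, seed=60_000 + c)
            fb = analysis.fear_bias_analysis(
                synth.records_by_subject(recs), alpha=alpha)
            any_sig += fb["level_tests"]["significant"].any()
        rate = 1 - any_sig / n_cohorts
        # spec-level expectation ~>= 94% non-significant, minus 3 binomial SE
        assert rate >= 0.94 - 3 * np.sqrt(0.06 * 0.94 / n_cohorts)

    def test_injected_fear_bias_recovered(self, session_spec):
        """A prior shifted toward 'fearful' produces negative criteria whose
        magnitude grows with the shift and shrinks with intensity."""
        means = {}
        for bias in (0.5, 0.65, 0.8):
            cfg = observer.ObserverConfig(seed=32, emotion_prior=(1 - bias, bias))
            recs = synth.simulate_cohort(
                synth.default_cohort(12, seed=70_001, p_miss=0.0),
                session_spec, cfg, seed=70_002)
            fb = analysis.fear_bias_analysis(synth.records_by_subject(recs))
            means[bias] = fb["level_tests"]["mean_c"]
        assert (means[0.8] < means[0.65]).all()
        assert (means[0.65][[5.0, 15.0]] < means[0.5][[5.0, 15.0]]).all()
        assert (means[0.8] < -0.1).all()

    def test_all_fearful_ea_criterion_boundary(self):
        df = pd.DataFrame([
            make_record(trial_index=i, ep_interval=1, resp_emotion_2="fearful")
            for i in range(20)
        ])
        c_ea = analysis.ea_criterion(df)
        assert c_ea == pytest.approx(-stats.norm.ppf(20 / 21))


class TestGroupTests:
    # 5 x 3 repeated-measures fixture; oracle computed independently from the
    # sums-of-squares and double-centered-covariance epsilon formulas
    FIXTURE = np.array([
        [45.0, 50.0, 55.0],
        [42.0, 42.0, 45.0],
        [36.0, 41.0, 43.0],
        [39.0, 35.0, 40.0],
        [51.0, 55.0, 59.0],
    ])

    def test_rm_anova_matches_hand_computed_oracle(self):
        r = analysis.rm_anova_gg(pd.DataFrame(self.FIXTURE))
        assert r.statistic == pytest.approx(8.427184466019396, rel=1e-9)
        assert r.epsilon_gg == pytest.approx(0.5857119196157436, rel=1e-6)
        assert r.df1 == pytest.approx(2 * r.epsilon_gg, rel=1e-6)
        assert r.p_value == pytest.approx(0.03433078006628272, rel=1e-5)

    def test_two_levels_reduce_to_paired_t(self):
        a, b = self.FIXTURE[:, 0], self.FIXTURE[:, 2]
        r = analysis.rm_anova_gg(pd.DataFrame(np.c_[a, b]))
        t = analysis.paired_ttest(b, a)
        assert r.statistic == pytest.approx(t.statistic**2)
        assert r.epsilon_gg == pytest.approx(1.0)

    def test_identical_columns_give_f_zero(self):
        x = np.tile(self.FIXTURE[:, :1], (1, 3))
        r = analysis.rm_anova_gg(pd.DataFrame(x))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_listwise_deletion_and_minimum_n(self):
        x = pd.DataFrame(self.FIXTURE.copy())
        x.iloc[0, 0] = np.nan
        r = analysis.rm_anova_gg(x)  # drops to 4 subjects, still valid
        assert np.isfinite(r.statistic)
        with pytest.raises(ValueError):
            analysis.rm_anova_gg(pd.DataFrame(self.FIXTURE[:2]))

    def test_paired_t_matches_scipy_and_zero_case(self):
        a, b = self.FIXTURE[:, 0], self.FIXTURE[:, 1]
        r = analysis.paired_ttest(a, b)
        t, p = stats.ttest_rel(a, b)
        assert r.statistic == pytest.approx(t) and r.p_value == pytest.approx(p)
        z = analysis.paired_ttest(a, a)
        assert z.statistic == 0.0 and z.p_value == 1.0
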