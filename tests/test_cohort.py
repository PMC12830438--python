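"""Synthetic cohort generator: calibration, degenerate cases, determinism."""

import numpy as np
import pandas as pd
import pytest

from rsvpdi import cohort, scoring
from rsvpdi.errors import ConfigurationError


class TestProfileCalibration:
    def test_propensity_moments_match_targets(self):
        """Mean/SD of the intrusion propensity hit the configured targets
        within 1% at n = 10,000."""
        profs = cohort.gen_profiles(cohort.GeneratorConfig(n_participants=10_000, seed=1))
        p = np.array([x.p_intrusion for x in profs])
        assert abs(p.mean() - 0.296) < 0.01
        assert abs(p.std(ddof=1) - 0.200) < 0.01

    def test_configured_loading_recovered(self):
        """A time-error loading of +.40 shows up as a propensity correlation
        within +-.05 at n = 10,000."""
        profs = cohort.gen_profiles(cohort.GeneratorConfig(n_participants=10_000, seed=2))
        p = np.array([x.p_intrusion for x in profs])
        te = np.array([x.mu_time_error for x in profs])
        assert abs(np.corrcoef(p, te)[0, 1] - 0.40) < 0.05

    def test_zero_dispersion_gives_constant_propensity(self):
        profs = cohort.gen_profiles(cohort.GeneratorConfig(n_participants=20, di_sd=0.0, seed=3))
        assert all(abs(x.p_intrusion - 0.296) < 1e-12 for x in profs)

    def test_infeasible_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            cohort.GeneratorConfig(di_mean=0.1, di_sd=0.5)

    def test_category_probabilities_form_simplex(self, small_profiles):
        for p in small_profiles:
            assert abs(p.p_correct + p.p_intrusion + p.p_other - 1.0) <= 1e-12
            assert 0.0 <= p.p_intrusion <= 1.0


class TestDiTrials:
    def _profile(self, pc, pi, po):
        return cohort.LatentProfile(
            participant_id="P0001", theta=0.0, p_correct=pc, p_intrusion=pi,
            p_other=po, t1_acc_true=0.8, t2_lag3_true=0.4, t2_lag7_true=0.8,
            mu_time_error=20.0, mu_rt=500.0, age=25.0, reading_swe=75.0,
            reading_pde=45.0)

    def test_pure_intruder_always_reports_posttarget(self):
        trials = cohort.gen_di_trials([self._profile(0, 1, 0)], 50, seed=4)
        assert (trials["response_id"] == trials["posttarget_id"]).all()

    def test_pure_guesser_never_reports_target_or_posttarget(self):
        trials = cohort.gen_di_trials([self._profile(0, 0, 1)], 200, seed=4)
        assert (trials["response_id"] != trials["target_id"]).all()
        assert (trials["response_id"] != trials["posttarget_id"]).all()

    def test_target_and_posttarget_distinct_digits(self, small_profiles):
        trials = cohort.gen_di_trials(small_profiles, 40, seed=6)
        assert (trials["target_id"] != trials["posttarget_id"]).all()
        assert trials["target_id"].between(2, 9).all()
        assert trials["posttarget_id"].between(2, 9).all()

    def test_observed_rate_sd_matches_total_variance_law(self, large_profiles):
        """SD of 60-trial observed DI rates equals sqrt(between-subject variance
        + mean binomial variance / 60), the law-of-total-variance oracle."""
        trials = cohort.gen_di_trials(large_profiles, 60, session=1, seed=99)
        obs = scoring.score_di_trials(trials)["di_rate"]
        p = np.array([x.p_intrusion for x in large_profiles])
        predicted = np.sqrt(p.var(ddof=1) + (p * (1 - p)).mean() / 60)
        assert obs.std(ddof=1) == pytest.approx(predicted, abs=0.01)

    def test_same_seed_reproduces_table(self, small_profiles):
        a = cohort.gen_di_trials(small_profiles, 30, seed=7)
        b = cohort.gen_di_trials(small_profiles, 30, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestAbTrials:
    def test_design_split_and_lag_balance(self, small_profiles):
        trials = cohort.gen_ab_trials(small_profiles, 96, seed=8)
        per = trials.groupby("participant_id")
        assert (per.apply(lambda g: (g["trial_type"] == "single").sum(),
                          include_groups=False) == 48).all()
        assert (per.apply(lambda g: (g["lag"] == 3.0).sum(), include_groups=False) == 24).all()
        assert (per.apply(lambda g: (g["lag"] == 7.0).sum(), include_groups=False) == 24).all()
        dual = trials["trial_type"] == "dual"
        assert trials.loc[dual, "t2_id"].notna().all()
        assert trials.loc[~dual, "t2_id"].isna().all()

    def test_indivisible_design_rejected(self, small_profiles):
        with pytest.raises(ConfigurationError):
            cohort.gen_ab_trials(small_profiles, 50, seed=8)

    def test_equal_lag_accuracies_give_zero_expected_blink(self):
        prof = cohort.LatentProfile(
            participant_id="P0001", theta=0.0, p_correct=0.7, p_intrusion=0.2,
            p_other=0.1, t1_acc_true=0.8, t2_lag3_true=0.6, t2_lag7_true=0.6,
            mu_time_error=20.0, mu_rt=500.0, age=25.0, reading_swe=75.0,
            reading_pde=45.0)
        trials = cohort.gen_ab_trials([prof], 4000, seed=9)
        ab = scoring.ab_scores(trials)["ab_magnitude"].iloc[0]
        assert abs(ab) < 0.05

    def test_default_cohort_blink_magnitude(self, large_profiles):
        """Calibrated lag-7 (.811) and lag-3 (.408) accuracies yield a mean
        observed blink magnitude near .403."""
        trials = cohort.gen_ab_trials(large_profiles[:2000], 96, seed=10)
        ab = scoring.ab_scores(trials)["ab_magnitude"]
        assert ab.mean() == pytest.approx(0.403, abs=0.02)


class TestTimeTrials:
    def test_zero_noise_profile_yields_exact_error(self):
        prof = cohort.LatentProfile(
            participant_id="P0001", theta=0.0, p_correct=0.7, p_intrusion=0.2,
            p_other=0.1, t1_acc_true=0.8, t2_lag3_true=0.4, t2_lag7_true=0.8,
            mu_time_error=60.0, mu_rt=500.0, age=25.0, reading_swe=75.0,
            reading_pde=45.0)
        trials = cohort.gen_time_trials([prof], 50, seed=11, within_sd=0.0, wild_fraction=0.0)
        from rsvpdi.time_judgment import circular_error
        err = circular_error(trials["cue_angle_deg"], trials["response_angle_deg"])
        assert np.allclose(err, 60.0)

    def test_wild_fraction_drives_extreme_error_rate(self, large_profiles):
        """With 2% uniform wild responses, the rate of |error| >= 160 deg is
        about .02 * 40/360 plus the (tiny) main-distribution tail."""
        from rsvpdi.time_judgment import circular_error
        profs = large_profiles[:100]
        trials = cohort.gen_time_trials(profs, 100, seed=12, wild_fraction=0.02)
        err = circular_error(trials["cue_angle_deg"], trials["response_angle_deg"])
        rate = (np.abs(err) >= 160).mean()
        analytic = 0.02 * 40.0 / 360.0
        assert analytic * 0.3 < rate < analytic + 0.01

    def test_angles_within_domain(self, small_profiles):
        trials = cohort.gen_time_trials(small_profiles, 30, seed=13)
        for col in ("cue_angle_deg", "response_angle_deg"):
            assert (trials[col] >= 0).all() and (trials[col] < 360).all()


class TestRtTrials:
    def test_condition_offsets_recovered(self, large_profiles):
        """Cueing offsets (+37 different, -36 same vs absent) survive
        generation and scoring within Monte-Carlo error."""
        trials = cohort.gen_rt_trials(large_profiles[:1500], "cueing", 200, seed=14)
        scores = scoring.rt_preprocess(trials)["scores"]
        diff = scores["mean_rt_different"].mean() - scores["mean_rt_absent"].mean()
        same = scores["mean_rt_same"].mean() - scores["mean_rt_absent"].mean()
        assert diff == pytest.approx(37.0, abs=4.0)
        assert same == pytest.approx(-36.0, abs=4.0)

    def test_condition_frequencies(self, small_profiles):
        trials = cohort.gen_rt_trials(small_profiles, "simon", 400, seed=15)
        frac = (trials["condition"] == "compatible").mean()
        assert frac == pytest.approx(0.75, abs=0.03)

    def test_unknown_task_rejected(self, small_profiles):
        with pytest.raises(ConfigurationError):
            cohort.gen_rt_trials(small_profiles, "stroop", 10, seed=16)

    def test_zero_noise_zero_offsets_degenerate(self):
        cfg = cohort.GeneratorConfig(
            rt_within_sd=0.0,
            cueing_offsets={"absent": 0.0, "different": 0.0, "same": 0.0})
        prof = cohort.LatentProfile(
            participant_id="P0001", theta=0.0, p_correct=0.7, p_intrusion=0.2,
            p_other=0.1, t1_acc_true=0.8, t2_lag3_true=0.4, t2_lag7_true=0.8,
            mu_time_error=20.0, mu_rt=500.0, age=25.0, reading_swe=75.0,
            reading_pde=45.0)
        trials = cohort.gen_rt_trials([prof], "cueing", 20, seed=17, config=cfg)
        assert np.allclose(trials["rt_ms"], 500.0)


class TestCohortBundle:
    def test_full_cohort_deterministic(self):
        cfg = cohort.GeneratorConfig(n_participants=20, seed=21)
        a = cohort.generate_cohort(cfg, di_trials_per_session=20, ab_trials=16,
                                   time_trials=10, rt_trials_per_task=20)
        b = cohort.generate_cohort(cfg, di_trials_per_session=20, ab_trials=16,
                                   time_trials=10, rt_trials_per_task=20)
        for name in ("di_trials", "ab_trials", "time_trials", "rt_trials", "covariates"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        assert getattr(a, "di_trials").to_csv(index=False) == getattr(b, "di_trials").to_csv(index=False)

    def test_mechanistic_generator_monotone_in_trait(self):
        """In the latency-threshold variant, slower traits produce more
        intrusions and fewer correct reports."""
        def prof(theta):
            return cohort.LatentProfile(
                participant_id=f"P{int(theta*10)+100:04d}", theta=theta, p_correct=0.7,
                p_intrusion=0.2, p_other=0.1, t1_acc_true=0.8, t2_lag3_true=0.4,
                t2_lag7_true=0.8, mu_time_error=20.0, mu_rt=500.0, age=25.0,
                reading_swe=75.0, reading_pde=45.0)
        slow, fast = prof(1.5), prof(-1.5)
        trials = cohort.mechanistic_di_trials([slow, fast], 2000, seed=22)
        rates = scoring.score_di_trials(trials).set_index("participant_id")["di_rate"]
        assert rates[slow.participant_id] > rates[fast.participant_id]
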