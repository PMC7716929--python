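import numpy as np
import pandas as pd
import pytest

from riskscreen.cohort import CohortProfile, generate_baseline_cohort
from riskscreen.model import MultiStateModel, default_truth_model
from riskscreen.trial import (
    CONTROL,
    INDIVIDUALISED,
    RandomisationScheme,
    TrialConfig,
    build_analysis_sets,
    randomise,
    run_trial,
)


def _null_truth():
    return MultiStateModel(transitions=(("R1R1", "SP"),), log_baseline=[-50.0])


def _full_attendance_profile(**kwargs):
    att = {
        (arm, g): 1.0
        for arm in (CONTROL, INDIVIDUALISED)
        for g in ("high", "medium", "low")
    }
    return CohortProfile(attendance=att, **kwargs)


class TestRandomise:
    def test_exact_balance_in_single_block(self):
        cohort = pd.DataFrame(
            {"id": range(4), "clinic": 0, "age_band": ">=16"}
        )
        scheme = RandomisationScheme(block_sizes_adult=(4,), seed=0)
        arms = randomise(cohort, scheme)
        assert (arms == CONTROL).sum() == 2
        assert (arms == INDIVIDUALISED).sum() == 2

    def test_same_seed_same_assignment(self):
        cohort = generate_baseline_cohort(300, seed=1)
        a = randomise(cohort, RandomisationScheme(seed=5))
        b = randomise(cohort, RandomisationScheme(seed=5))
        assert (a == b).all()

    def test_overall_imbalance_bounded(self):
        """Worst-case prefix imbalance is half the largest block per stratum."""
        cohort = generate_baseline_cohort(10_000, seed=2)
        arms = randomise(cohort, RandomisationScheme(seed=3))
        n_strata = cohort.groupby(["clinic", "age_band"]).ngroups
        imbalance = abs((arms == CONTROL).sum() - (arms == INDIVIDUALISED).sum())
        assert imbalance <= n_strata * 3

    def test_missing_stratum_rejected(self):
        cohort = pd.DataFrame({"id": [0], "clinic": [np.nan], "age_band": [">=16"]})
        with pytest.raises(ValueError):
            randomise(cohort, RandomisationScheme(seed=0))

    def test_odd_block_size_rejected(self):
        with pytest.raises(ValueError):
            RandomisationScheme(block_sizes_adult=(3,))


class TestRunTrial:
    def test_null_truth_control_arm_two_followups_no_events(self):
        """With no disease and full attendance, controls attend at 12 and 24."""
        profile = _full_attendance_profile()
        cohort = generate_baseline_cohort(60, profile, seed=4)
        arms = pd.Series([CONTROL] * len(cohort))
        cfg = TrialConfig(withdrawals=False, false_positive_rate=0.0,
                          group_probs_override={"low": 1.0})
        trial = run_trial(cohort, arms, None, _null_truth(), profile, cfg, seed=0)
        assert (trial.participants["n_invited"] == 2).all()
        assert (trial.participants["n_attended"] == 2).all()
        assert not trial.visits["screen_positive"].any()
        assert sorted(trial.visits["invitation_time"].unique()) == [12.0, 24.0]

    def test_all_low_risk_individualised_halves_appointments(self):
        """Low-risk recall at 24 months means one follow-up instead of two."""
        profile = _full_attendance_profile()
        cohort = generate_baseline_cohort(120, profile, seed=5)
        arms = pd.Series([CONTROL, INDIVIDUALISED] * 60)
        cfg = TrialConfig(withdrawals=False, false_positive_rate=0.0,
                          group_probs_override={"low": 1.0})
        trial = run_trial(cohort, arms, None, _null_truth(), profile, cfg, seed=1)
        by_arm = trial.participants.groupby("arm")["n_attended"].sum()
        assert (
            trial.participants.loc[
                trial.participants["arm"] == INDIVIDUALISED, "n_invited"
            ]
            == 1
        ).all()
        assert by_arm[INDIVIDUALISED] / by_arm[CONTROL] == pytest.approx(0.5)

    def test_counts_conservation_per_arm(self):
        """Attended + not attended + unresolved = randomised, per arm."""
        profile = CohortProfile()
        cohort = generate_baseline_cohort(800, profile, seed=6)
        arms = randomise(cohort, RandomisationScheme(seed=7))
        trial = run_trial(cohort, arms, default_truth_model(), default_truth_model(),
                          profile, TrialConfig(), seed=8)
        parts = trial.participants
        for arm in (CONTROL, INDIVIDUALISED):
            sub = parts[parts["arm"] == arm]
            attended = (sub["first_followup_attended"] == True).sum()  # noqa: E712
            missed = (sub["first_followup_attended"] == False).sum()  # noqa: E712
            unresolved = sub["first_followup_attended"].isna().sum()
            assert attended + missed + unresolved == len(sub)

    def test_confirmed_stdr_exits_recall(self):
        """A confirmed screen-positive participant gets no further invitations."""
        profile = _full_attendance_profile()
        # disease progresses fast and every screen-positive is confirmed
        truth = MultiStateModel(transitions=(("R1R1", "SP"),), log_baseline=[np.log(0.2)])
        cohort = generate_baseline_cohort(100, profile, seed=9)
        cohort["state0"] = "R1R1"
        arms = pd.Series([CONTROL] * len(cohort))
        cfg = TrialConfig(withdrawals=False, stdr_confirm_prob=1.0,
                          false_positive_rate=0.0, group_probs_override={"high": 1.0})
        trial = run_trial(cohort, arms, None, truth, profile, cfg, seed=10)
        v = trial.visits
        for pid, sub in v.groupby("id"):
            confirmed = sub[sub["stdr_confirmed"]]
            if len(confirmed):
                t_conf = confirmed["invitation_time"].min()
                assert not (sub["invitation_time"] > t_conf).any()

    def test_withdrawal_truncates_visits(self):
        profile = _full_attendance_profile(withdrawal_per_annum=0.6)
        cohort = generate_baseline_cohort(300, profile, seed=11)
        arms = pd.Series([CONTROL] * len(cohort))
        cfg = TrialConfig(group_probs_override={"low": 1.0}, false_positive_rate=0.0)
        trial = run_trial(cohort, arms, None, _null_truth(), profile, cfg, seed=12)
        merged = trial.visits.merge(
            trial.participants[["id", "withdrawal_time"]], on="id"
        )
        wt = merged["withdrawal_time"].astype(float).fillna(np.inf)
        assert (merged["invitation_time"] < wt + 1e-9).all()

    def test_individualised_invitations_are_sums_of_intervals(self):
        profile = _full_attendance_profile()
        cohort = generate_baseline_cohort(150, profile, seed=13)
        arms = pd.Series([INDIVIDUALISED] * len(cohort))
        cfg = TrialConfig(withdrawals=False, false_positive_rate=0.0)
        trial = run_trial(cohort, arms, default_truth_model(), default_truth_model(),
                          profile, cfg, seed=14)
        for pid, sub in trial.visits.groupby("id"):
            t = 0.0
            for _, row in sub.sort_values("invitation_time").iterrows():
                assert row["invitation_time"] == pytest.approx(
                    t + (row["invitation_time"] - t)
                )
                assert float(row["invitation_time"] - t) in (6.0, 12.0, 24.0)
                t = row["invitation_time"]


class TestAnalysisSets:
    def test_no_deviations_no_withdrawals_pp_equals_itt(self):
        profile = _full_attendance_profile()
        cohort = generate_baseline_cohort(200, profile, seed=15)
        arms = randomise(cohort, RandomisationScheme(seed=16))
        cfg = TrialConfig(withdrawals=False, false_positive_rate=0.0,
                          group_probs_override={"low": 1.0})
        trial = run_trial(cohort, arms, None, _null_truth(), profile, cfg, seed=17)
        sets = build_analysis_sets(trial)
        pp = sets.table("attendance", "per_protocol")
        itt = sets.table("attendance", "itt")
        assert pp == itt

    def test_itt_superset_of_pp(self):
        profile = CohortProfile()
        cohort = generate_baseline_cohort(1000, profile, seed=18)
        arms = randomise(cohort, RandomisationScheme(seed=19))
        cfg = TrialConfig(deviation_rate=0.05)
        trial = run_trial(cohort, arms, default_truth_model(), default_truth_model(),
                          profile, cfg, seed=20)
        parts = trial.participants
        assert (parts["per_protocol"] <= parts["itt"]).all()
        sets = build_analysis_sets(trial)
        pp = sets.table("attendance", "per_protocol")
        itt = sets.table("attendance", "itt")
        assert itt.n_individualised >= pp.n_individualised
        assert itt.n_control >= pp.n_control

    def test_deviations_excluded_from_pp_only(self):
        profile = _full_attendance_profile()
        cohort = generate_baseline_cohort(400, profile, seed=21)
        arms = pd.Series([INDIVIDUALISED] * len(cohort))
        cfg = TrialConfig(withdrawals=False, deviation_rate=0.3,
                          false_positive_rate=0.0)
        trial = run_trial(cohort, arms, default_truth_model(), default_truth_model(),
                          profile, cfg, seed=22)
        parts = trial.participants
        dev = parts["deviation"]
        assert dev.any()
        assert not parts.loc[dev, "per_protocol"].any()
        assert parts.loc[dev, "itt"].all()
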