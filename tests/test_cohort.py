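"""Cohort construction: inclusion order, ITT groups, imputation,
subsets, descriptive tables and the paired >95% comparison."""

import datetime as dt
import itertools

import numpy as np
import pytest

from artcov.cohort import (
    GROUP_EXPOSED,
    GROUP_UNEXPOSED,
    GROUP_UNKNOWN,
    CohortError,
    ExclusionTally,
    assign_group,
    baseline_table,
    build_cohort,
    impute_missing,
    mcnemar_gt95,
    select_subset,
)

from conftest import make_patient, make_rx

D = dt.date


def eligible_patient(i, **kw):
    return make_patient(patient_id=f"P{i:05d}", **kw)


def rx_for(i, issue, duration=180, **kw):
    return make_rx(issue, duration, patient_id=f"P{i:05d}", **kw)


class TestBuildCohort:
    def test_toy_tally_applies_rules_in_order(self, config):
        """5 screened: one under-age, one enrolled after obs start, three in."""
        patients = [
            eligible_patient(1, birth_date=D(1995, 6, 1)),  # age 17.4 at data_start
            eligible_patient(2, enrollment_date=D(2013, 8, 1)),
            eligible_patient(3),
            eligible_patient(4),
            eligible_patient(5),
        ]
        rxs = [rx_for(i, D(2013, 1, 1)) for i in range(1, 6)]
        rxs += [rx_for(i, D(2013, 7, 15)) for i in range(1, 6)]
        members, tally = build_cohort(patients, rxs, config)
        assert (
            tally.total_screened,
            tally.under_age,
            tally.no_rx_in_observation,
            tally.not_enrolled_before,
            tally.delayed_phone_capture,
            tally.no_observation_time,
            tally.included,
        ) == (5, 1, 0, 1, 0, 0, 3)

    def test_first_matching_reason_counts_once(self, config):
        """A patient failing several criteria lands under the first one."""
        patients = [
            eligible_patient(
                1, birth_date=D(1999, 1, 1), enrollment_date=D(2013, 10, 1)
            )
        ]
        members, tally = build_cohort(patients, [rx_for(1, D(2013, 8, 1), 30)], config)
        assert tally.under_age == 1 and tally.not_enrolled_before == 0

    def test_no_rx_in_observation_counts_dedup_survivors(self, config):
        """A window whose only in-period record is a re-recorded balance of a
        6-month script does not satisfy the prescription criterion."""
        patients = [eligible_patient(1)]
        rxs = [
            rx_for(1, D(2013, 5, 1), 180),
            rx_for(1, D(2013, 7, 30), 90),  # duplicate: inside the 180-day span
        ]
        members, tally = build_cohort(patients, rxs, config)
        assert tally.no_rx_in_observation == 1 and tally.included == 0

    def test_delayed_phone_capture_excluded(self, config):
        patients = [
            eligible_patient(1, phone_capture_date=D(2013, 7, 2)),
            eligible_patient(2),
        ]
        rxs = [rx_for(1, D(2013, 8, 1)), rx_for(2, D(2013, 8, 1))]
        members, tally = build_cohort(patients, rxs, config)
        assert tally.delayed_phone_capture == 1 and tally.included == 1

    def test_transfer_before_window_is_no_observation_time(self, config):
        """Transfer out before the first in-period script ends: the patient
        has an in-period prescription but no observable day."""
        patients = [eligible_patient(1, transfer_out_date=D(2013, 8, 15))]
        members, tally = build_cohort(patients, [rx_for(1, D(2013, 8, 1), 180)], config)
        assert tally.no_observation_time == 1 and tally.included == 0

    def test_all_eligible_means_included_equals_screened(self, config):
        patients = [eligible_patient(i) for i in range(1, 4)]
        rxs = [rx_for(i, D(2013, 8, 1)) for i in range(1, 4)]
        members, tally = build_cohort(patients, rxs, config)
        assert tally.included == tally.total_screened == 3

    def test_opt_out_is_ignored_for_group_assignment(self, config):
        """Intention to treat: opting out after launch leaves a patient
        Exposed."""
        patients = [
            eligible_patient(
                1, phone_capture_date=D(2013, 6, 15), opt_out_date=D(2013, 10, 1)
            )
        ]
        members, _ = build_cohort(patients, [rx_for(1, D(2013, 8, 1))], config)
        assert members[0].group == GROUP_EXPOSED

    def test_group_assignment_is_pure_and_order_free(self, config):
        patients = [
            eligible_patient(1, phone_status="available"),
            eligible_patient(2, phone_status="absent"),
            eligible_patient(3, phone_status="unknown"),
        ]
        rxs = [rx_for(i, D(2013, 8, 1)) for i in (1, 2, 3)]
        expected = {
            "P00001": GROUP_EXPOSED,
            "P00002": GROUP_UNEXPOSED,
            "P00003": GROUP_UNKNOWN,
        }
        for perm in itertools.permutations(patients):
            members, _ = build_cohort(list(perm), rxs, config)
            assert {m.patient.patient_id: m.group for m in members} == expected

    def test_tally_conserves_on_synthetic_run(self, config, behavioral_members):
        members, tally, _ = behavioral_members
        tally.check()
        assert tally.included == len(members)

    def test_tally_check_rejects_nonconserving_counts(self):
        bad = ExclusionTally(
            total_screened=10,
            under_age=1,
            no_rx_in_observation=0,
            not_enrolled_before=0,
            delayed_phone_capture=0,
            no_observation_time=0,
            included=10,
        )
        with pytest.raises(CohortError, match="conserve"):
            bad.check()


class TestImputation:
    def _members(self, config, patients, rxs):
        members, _ = build_cohort(patients, rxs, config)
        return members

    def test_mean_substitution(self, config):
        patients = [
            eligible_patient(1, birth_date=D(1982, 11, 4)),  # age 30.0
            eligible_patient(2, birth_date=D(1972, 11, 4)),  # age 40.0
            eligible_patient(3, birth_date=None),
        ]
        rxs = [rx_for(i, D(2013, 8, 1)) for i in (1, 2, 3)]
        members = self._members(config, patients, rxs)
        impute_missing(members)
        by_id = {m.patient.patient_id: m for m in members}
        assert by_id["P00003"].covariates.age_years == pytest.approx(35.0, abs=0.01)
        assert by_id["P00003"].covariates.missing_any
        assert not by_id["P00001"].covariates.missing_any

    def test_binary_covariate_gets_fractional_mean(self, config):
        genders = ["female", "female", "male", None]
        patients = [
            eligible_patient(i + 1, gender=g) for i, g in enumerate(genders)
        ]
        rxs = [rx_for(i, D(2013, 8, 1)) for i in range(1, 5)]
        members = self._members(config, patients, rxs)
        impute_missing(members)
        imputed = [m for m in members if m.patient.gender is None][0]
        assert imputed.covariates.female == pytest.approx(2 / 3)

    def test_no_missing_is_identity(self, config):
        patients = [eligible_patient(i) for i in (1, 2)]
        rxs = [rx_for(i, D(2013, 8, 1)) for i in (1, 2)]
        members = self._members(config, patients, rxs)
        before = [(m.covariates.age_years, m.covariates.female) for m in members]
        impute_missing(members)
        after = [(m.covariates.age_years, m.covariates.female) for m in members]
        assert before == after
        assert not any(m.covariates.missing_any for m in members)

    def test_mean_preserved_by_substitution(self, config, behavioral_members):
        members, _, _ = behavioral_members
        observed = [
            m.covariates.age_years
            for m in members
            if not m.covariates.missing_any or m.patient.birth_date is not None
        ]
        all_ages = [m.covariates.age_years for m in members]
        # members with imputed age carry exactly the mean of observed ages
        assert np.mean(all_ages) == pytest.approx(np.mean(observed), rel=1e-12)

    def test_all_missing_raises(self, config):
        patients = [eligible_patient(1, birth_date=None)]
        members = self._members(config, patients, [rx_for(1, D(2013, 8, 1))])
        with pytest.raises(CohortError, match="missing for all"):
            impute_missing(members)


class TestPreProgramCoverage:
    def test_fully_covered_baseline_is_one(self, config):
        patients = [eligible_patient(1)]
        members, _ = build_cohort(patients, [rx_for(1, D(2013, 1, 1), 180),
                                             rx_for(1, D(2013, 7, 1), 180)], config)
        assert members[0].pre_program_coverage == pytest.approx(1.0)

    def test_window_after_program_start_has_absent_baseline(self, config):
        patients = [eligible_patient(1)]
        members, _ = build_cohort(patients, [rx_for(1, D(2013, 10, 1), 30)], config)
        assert members[0].pre_program_coverage is None

    def test_partial_baseline_is_direct_ratio(self, config):
        """Coverage ends 10 days into the 70-day pre-program stretch of a
        window opening 2013-07-01 -> 60/70 observed."""
        patients = [eligible_patient(1)]
        rxs = [
            rx_for(1, D(2013, 1, 1), 180),      # window opens at obs_start
            rx_for(1, D(2013, 6, 30), 60),      # covers through 2013-08-28
            rx_for(1, D(2013, 9, 9), 180),      # resumes at program start
        ]
        members, _ = build_cohort(patients, rxs, config)
        # pre-program days 2013-07-01..2013-09-08 = 70; covered 07-01..08-28 = 59
        assert members[0].pre_program_coverage == pytest.approx(59 / 70)


class TestSubsets:
    def _member(self, config, i, rxs, **kw):
        members, _ = build_cohort([eligible_patient(i, **kw)], rxs, config)
        return members[0]

    def test_full_baseline_excluded_from_below100(self, config):
        m_full = self._member(config, 1, [rx_for(1, D(2013, 1, 1), 180),
                                          rx_for(1, D(2013, 7, 1), 180)])
        m_gap = self._member(config, 2, [rx_for(2, D(2013, 1, 1), 180),
                                         rx_for(2, D(2013, 7, 20), 180)])
        m_absent = self._member(config, 3, [rx_for(3, D(2013, 10, 1), 90)])
        selected = select_subset([m_full, m_gap, m_absent], "below_100_baseline", config)
        assert [m.patient.patient_id for m in selected] == ["P00002"]

    def test_recent_initiators_boundary(self, config):
        old = self._member(config, 1, [rx_for(1, D(2013, 8, 1))],
                           art_start_date=D(2011, 6, 1))
        recent = self._member(config, 2, [rx_for(2, D(2013, 8, 1))],
                              art_start_date=D(2012, 1, 1))  # 1.69 y before launch
        selected = select_subset([old, recent], "recent_initiators", config)
        assert [m.patient.patient_id for m in selected] == ["P00002"]

    def test_unknown_subset_name_rejected(self, config):
        with pytest.raises(CohortError, match="unknown subset"):
            select_subset([], "everyone", config)


class TestBaselineTable:
    def test_identical_groups_give_p_one(self, config):
        """Identical Exposed/Unexposed/Unknown compositions carry no
        evidence of difference: every defined p-value is 1."""
        patients, rxs = [], []
        i = 1
        for status in ("available", "absent", "unknown"):
            for birth, gender in ((D(1975, 3, 15), "female"), (D(1965, 1, 1), "male")):
                patients.append(
                    eligible_patient(i, phone_status=status, birth_date=birth, gender=gender)
                )
                rxs.append(rx_for(i, D(2013, 8, 1)))
                i += 1
        members, _ = build_cohort(patients, rxs, config)
        table = baseline_table(members, config)
        pvals = table[["p_all", "p_exposed_vs_unexposed"]].to_numpy(dtype=float)
        defined = pvals[np.isfinite(pvals)]
        assert np.allclose(defined, 1.0)

    def test_separated_means_and_proportions_detected(self, config, behavioral_members):
        """Large constructed contrasts produce tiny ANOVA/chi-squared
        p-values through the table's own code path."""
        from artcov.cohort import _anova_p, _chi2_p

        rng = np.random.default_rng(5)
        a = rng.normal(30, 1, 100)
        b = rng.normal(50, 1, 100)
        assert _anova_p([a, b]) < 1e-3
        assert _chi2_p(np.array([[50, 90], [50, 10]])) < 1e-3

    def test_table_rows_cover_printed_structure(self, config, behavioral_members):
        members, _, _ = behavioral_members
        table = baseline_table(members, config)
        assert table["variable"].tolist() == [
            "Age in years (IQR)",
            "Female",
            "ART duration in years (IQR)",
            "Prescription length in days (IQR)",
            "1-month prescriptions",
            "2-month prescriptions",
            "3-month prescriptions",
            "6-month prescriptions",
            "First line regimen",
            "Fixed dose combination",
            "No pre-program observation time",
            "Transfer out during observation",
        ]


class TestMcNemar:
    def _paired_members(self, config, n_lost, n_gained, n_concordant):
        """Members engineered to land in chosen discordance cells."""
        members = []
        i = 1
        # concordant high-high: continuous coverage
        for _ in range(n_concordant):
            members.append(
                build_cohort(
                    [eligible_patient(i)],
                    [rx_for(i, D(2013, 1, 1), 180), rx_for(i, D(2013, 6, 30), 180),
                     rx_for(i, D(2013, 12, 27), 180)],
                    config,
                )[0][0]
            )
            i += 1
        # lost: perfect pre, long during-program gap
        for _ in range(n_lost):
            members.append(
                build_cohort(
                    [eligible_patient(i)],
                    [rx_for(i, D(2013, 1, 1), 180), rx_for(i, D(2013, 6, 30), 90),
                     rx_for(i, D(2014, 1, 15), 90)],
                    config,
                )[0][0]
            )
            i += 1
        # gained: pre-program gap, continuous during
        for _ in range(n_gained):
            members.append(
                build_cohort(
                    [eligible_patient(i)],
                    [rx_for(i, D(2013, 1, 1), 180), rx_for(i, D(2013, 7, 20), 180),
                     rx_for(i, D(2014, 1, 10), 180)],
                    config,
                )[0][0]
            )
            i += 1
        return members

    def test_no_discordance_gives_p_one(self, config):
        members = self._paired_members(config, 0, 0, 4)
        stat, p, table = mcnemar_gt95(members)
        assert p == 1.0
        assert table[1, 1] == 4

    def test_one_vs_seven_exact_two_sided(self, config):
        """1 vs 7 discordant pairs: exact two-sided binomial p = 0.0703."""
        members = self._paired_members(config, 7, 1, 2)
        stat, p, table = mcnemar_gt95(members)
        assert (table[1, 0], table[0, 1]) == (7, 1)
        assert p == pytest.approx(0.0703125, abs=1e-6)

    def test_uniform_direction_ten_pairs(self, config):
        """b=0, c=10 -> exact p = 2 * 0.5^10."""
        members = self._paired_members(config, 10, 0, 0)
        stat, p, table = mcnemar_gt95(members)
        assert p == pytest.approx(2 * 0.5**10, abs=1e-9)

    def test_members_without_both_periods_are_excluded(self, config):
        with_pair = self._paired_members(config, 0, 0, 2)
        only_during = build_cohort(
            [eligible_patient(99)], [rx_for(99, D(2013, 10, 1), 90)], config
        )[0]
        stat, p, table = mcnemar_gt95(with_pair + only_during)
        assert table.sum() == 2
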