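"""Start-of-follow-up rules, eligibility accounting, exit resolution,
analytic dataset assembly, cross-sectional extracts, and frequency
summaries."""

from datetime import date

import numpy as np
import pytest

from cohortforge import (build_cohort_dataset, build_cross_sectional_dataset,
                         determine_start, resolve_exit, summarize_frequencies)
from cohortforge.cohort import StartRule, parse_followup
from cohortforge.errors import SpecificationError
from cohortforge.selection import SelectionSpec

from _oracle import resolve_all
from _specgen import oracle_params, random_spec
from conftest import build_toy_tables, make_spec


class TestDetermineStart:
    def test_baseline_is_enrollment(self, toy_six):
        out = determine_start(toy_six.participants, StartRule("baseline"))
        assert (out == toy_six.participants["enrollment_date"]).all()

    def test_skipped_survey_wave_is_ineligible(self):
        tables = build_toy_tables([
            {"participant_id": "T1", "survey3_date": "2001-06-01"},
            {"participant_id": "T2"},
        ])
        out = determine_start(tables.participants, StartRule("survey_k", k=3))
        assert out.tolist() == ["2001-06-01", ""]

    def test_fixed_date_accepts_us_format_via_spec(self):
        spec = make_spec(start={"rule": "fixed_date", "date": "01/01/2005"})
        assert spec.start["date"] == "2005-01-01"
        followup = parse_followup(spec)
        assert followup.start_rule.date == date(2005, 1, 1)

    def test_fixed_date_gates_death_and_linkage(self):
        tables = build_toy_tables([
            {"participant_id": "T1"},
            {"participant_id": "T2", "vital_status": "dead",
             "date_of_death": "2003-01-01"},
            {"participant_id": "T3", "enrollment_date": "1999-08-01"},
        ])
        out = determine_start(tables.participants,
                              StartRule("fixed_date", date=date(2005, 1, 1)))
        assert out.tolist() == ["2005-01-01", "", "2005-01-01"]

    def test_fixed_date_outside_window_is_specification_error(self, toy_six):
        with pytest.raises(SpecificationError, match="window"):
            determine_start(toy_six.participants,
                            StartRule("fixed_date", date=date(1990, 1, 1)))


class TestResolveExit:
    def test_event_beats_death_on_same_day(self):
        exit_date, status = resolve_exit(
            "2000-01-01", [("2005-03-01", "event"), ("2005-03-01", "death"),
                           ("2010-12-31", "admin_censor")])
        assert (exit_date, status) == ("2005-03-01", "event")

    def test_admin_candidate_alone(self):
        assert resolve_exit("2000-01-01", [("2010-12-31", "admin_censor")]) == \
            ("2010-12-31", "admin_censor")

    def test_earliest_candidate_wins(self):
        exit_date, status = resolve_exit(
            "2000-01-01", [("2004-06-01", "death"), ("2003-05-10", "surgery"),
                           ("2010-12-31", "admin_censor")])
        assert (exit_date, status) == ("2003-05-10", "surgery")

    def test_candidates_before_start_ignored(self):
        exit_date, status = resolve_exit(
            "2005-01-01", [("2003-05-10", "surgery"),
                           ("2010-12-31", "admin_censor")])
        assert status == "admin_censor"

    def test_missing_admin_candidate_is_error(self):
        with pytest.raises(SpecificationError):
            resolve_exit("2005-01-01", [("2003-05-10", "surgery")])


class TestToySixCohort:
    def test_statuses_resolve_exactly_as_constructed(self, toy_six, toy_six_spec):
        frame, log = build_cohort_dataset(toy_six, toy_six_spec)
        by_id = frame.set_index("participant_id")
        assert "T1" not in by_id.index          # prevalent cancer
        assert by_id.loc["T2", "status"] == "other_cancer"
        assert by_id.loc["T2", "exit_date"] == "2003-06-15"
        assert by_id.loc["T3", "status"] == "event"
        assert by_id.loc["T3", "event_site"] == "C50.9"
        assert by_id.loc["T4", "status"] == "death"
        assert by_id.loc["T5", "status"] == "surgery"
        assert by_id.loc["T5", "exit_date"] == "2003-05-10"
        assert by_id.loc["T6", "status"] == "admin_censor"
        assert by_id.loc["T6", "exit_date"] == "2010-12-31"

    def test_attrition_log_accounts_for_every_exclusion(self, toy_six, toy_six_spec):
        frame, log = build_cohort_dataset(toy_six, toy_six_spec)
        assert log.source_n == 6
        assert log.final_n == len(frame) == 5
        assert log.source_n - log.total_excluded() == len(frame)
        prevalent = [r for r in log.rows if "prevalent" in r[0]]
        assert prevalent[0][1] == 1

    def test_prevalent_toggle_retains_participant(self, toy_six):
        spec = make_spec(censoring={"end_of_study": "2010-12-31",
                                    "exclude_prevalent_cancer": False})
        frame, _ = build_cohort_dataset(toy_six, spec)
        assert "T1" in set(frame["participant_id"])

    def test_surgery_censoring_beats_later_diagnosis(self, toy_six, toy_six_spec):
        """A bilateral mastectomy before the breast-cancer diagnosis ends
        follow-up at the surgery date."""
        frame, _ = build_cohort_dataset(toy_six, toy_six_spec)
        row = frame.set_index("participant_id").loc["T5"]
        assert row["status"] == "surgery"
        assert row["exit_date"] == "2003-05-10" < "2004-01-01"

    def test_person_days_are_calendar_day_differences(self, toy_six, toy_six_spec):
        frame, _ = build_cohort_dataset(toy_six, toy_six_spec)
        row = frame.set_index("participant_id").loc["T2"]
        expected = (date(2003, 6, 15) - date(1996, 1, 15)).days
        assert row["person_days"] == expected

    def test_essential_covariates_present(self, toy_six, toy_six_spec):
        frame, _ = build_cohort_dataset(toy_six, toy_six_spec)
        from cohortforge import essential_set
        names = {e.name for e in essential_set(toy_six.catalog)}
        assert names <= set(frame.columns)


class TestFollowupWindow:
    def test_first_to_last_enrollment_window_person_days(self):
        """Follow-up from the study's first to last baseline-survey date
        spans 1393 days."""
        tables = build_toy_tables([
            {"participant_id": "T1", "enrollment_date": "1995-10-27"},
        ])
        spec = make_spec(censoring={"end_of_study": "1999-08-20"},
                         endpoint={"type": "none"})
        frame, _ = build_cohort_dataset(tables, spec)
        assert frame["person_days"].iloc[0] == 1393
        assert (date(1999, 8, 20) - date(1995, 10, 27)).days == 1393

    def test_event_inside_window(self, mid_tables):
        spec = make_spec(censoring={"end_of_study": "2010-12-31"})
        frame, _ = build_cohort_dataset(mid_tables, spec)
        events = frame[frame["status"] == "event"]
        assert (events["start_date"] <= events["event_date"]).all()
        assert (events["event_date"] <= "2010-12-31").all()
        assert (events["event_date"] == events["exit_date"]).all()

    def test_no_exposure_after_surgery(self, mid_tables):
        from cohortforge import surgery_censor_dates
        spec = make_spec()
        frame, _ = build_cohort_dataset(mid_tables, spec)
        surgery = surgery_censor_dates(mid_tables.hospitalizations, "breast")
        merged = frame.join(surgery, on="participant_id")
        has = merged["surgery_date"].notna()
        assert (merged.loc[has, "exit_date"] <= merged.loc[has, "surgery_date"]).all()


class TestOracleEquivalence:
    def test_exit_records_match_brute_force_scan(self, mid_tables):
        rng = np.random.default_rng(101)
        for _ in range(5):
            spec = random_spec(rng)
            frame, _ = build_cohort_dataset(mid_tables, spec)
            expected = resolve_all(mid_tables, oracle_params(spec))
            got = {row.participant_id: (row.start_date, row.exit_date, row.status)
                   for row in frame.itertuples(index=False)}
            assert got == expected


class TestMonotonicity:
    def test_adding_exclusions_never_increases_person_time(self, mid_tables):
        base_spec = make_spec(censoring={"end_of_study": "2015-12-31",
                                         "censor_other_cancers": False,
                                         "exclude_prevalent_cancer": False})
        base, _ = build_cohort_dataset(mid_tables, base_spec)
        for censoring in (
                {"end_of_study": "2015-12-31", "censor_other_cancers": True,
                 "exclude_prevalent_cancer": False},
                {"end_of_study": "2015-12-31", "censor_other_cancers": False,
                 "exclude_prevalent_cancer": True},
                {"end_of_study": "2015-12-31"},
        ):
            stricter, _ = build_cohort_dataset(mid_tables,
                                               make_spec(censoring=censoring))
            assert len(stricter) <= len(base)
            assert stricter["person_days"].sum() <= base["person_days"].sum()

    def test_extra_criterion_logged_and_monotone(self, mid_tables):
        spec = make_spec()
        base, base_log = build_cohort_dataset(mid_tables, spec)
        drop = set(base["participant_id"].iloc[:10])
        smaller, log = build_cohort_dataset(mid_tables, spec,
                                            extra_criteria=[("pilot exclusion",
                                                             drop)])
        assert len(smaller) == len(base) - 10
        assert any(r[0] == "pilot exclusion" for r in log.rows)


class TestCrossSectional:
    def _spec(self, ref="2010-12-31", endpoint=None):
        return make_spec(
            endpoint=endpoint if endpoint is not None else
            {"type": "cancer", "site_prefixes": ["C50"]},
            metadata={"project": "xs", "design": "cross_sectional",
                      "reference_date": ref})

    def test_dead_before_reference_excluded(self, toy_six):
        frame, _ = build_cross_sectional_dataset(toy_six, self._spec())
        assert "T4" not in set(frame["participant_id"])

    def test_no_endpoint_section_gives_covariate_only_extract(self, toy_six):
        frame, _ = build_cross_sectional_dataset(
            toy_six, self._spec(endpoint={"type": "none"}))
        assert "endpoint_case" not in frame.columns
        assert "person_days" not in frame.columns

    def test_indicator_counts_match_cohort_events_among_survivors(self, mid_tables):
        """With censoring off, cases at the reference date are exactly the
        cohort design's events among participants alive at that date."""
        ref = "2015-12-31"
        cohort_spec = make_spec(
            censoring={"end_of_study": ref, "censor_other_cancers": False,
                       "exclude_prevalent_cancer": False})
        cohort, _ = build_cohort_dataset(mid_tables, cohort_spec)
        xs, _ = build_cross_sectional_dataset(
            mid_tables, make_spec(
                censoring={"end_of_study": ref},
                metadata={"project": "xs", "design": "cross_sectional",
                          "reference_date": ref}))
        p = mid_tables.participants.set_index("participant_id")
        alive_at_ref = cohort["participant_id"].map(
            lambda pid: p.loc[pid, "date_of_death"] == ""
            or p.loc[pid, "date_of_death"] >= ref)
        cohort_events = set(
            cohort.loc[(cohort["status"] == "event") & alive_at_ref,
                       "participant_id"])
        xs_cases = set(xs.loc[xs["endpoint_case"] == "1", "participant_id"])
        # the cross-sectional view may add prevalent cases the cohort
        # design excluded, never lose incident ones
        assert cohort_events <= xs_cases

    def test_reference_before_enrollment_warns_and_is_empty(self, toy_six):
        with pytest.warns(UserWarning, match="reference"):
            frame, _ = build_cross_sectional_dataset(toy_six,
                                                     self._spec(ref="1995-01-02"))
        assert len(frame) == 0


class TestFrequencySummary:
    def test_endpoint_only_counts_all_qualifying_participants(self, toy_six):
        spec = SelectionSpec({"endpoint": {"type": "cancer",
                                           "site_prefixes": ["C50"]},
                              "metadata": {"project": "t", "design": "cohort"}})
        summary = summarize_frequencies(toy_six, spec)
        assert summary.eligible_n == 6
        assert summary.event_n == 3          # T1, T3, T5 carry C50 events
        assert summary.endpoint_by_group.get("Breast") == 3

    def test_empty_spec_counts_everyone(self, toy_six):
        spec = SelectionSpec({"metadata": {"project": "t", "design": "cohort"}})
        summary = summarize_frequencies(toy_six, spec)
        assert summary.eligible_n == 6
        assert summary.event_n is None

    def test_full_spec_matches_dataset(self, toy_six, toy_six_spec):
        frame, _ = build_cohort_dataset(toy_six, toy_six_spec)
        summary = summarize_frequencies(toy_six, toy_six_spec)
        assert summary.eligible_n == len(frame)
        assert summary.event_n == int((frame["status"] == "event").sum())

    def test_adding_exclusions_never_increases_eligible_n(self, mid_tables):
        loose = summarize_frequencies(
            mid_tables, make_spec(censoring={"end_of_study": "2015-12-31",
                                             "exclude_prevalent_cancer": False}))
        strict = summarize_frequencies(mid_tables, make_spec())
        assert strict.eligible_n <= loose.eligible_n

    def test_categorical_counts_include_missing_and_sum(self, toy_six):
        spec = SelectionSpec({"metadata": {"project": "t", "design": "cohort"}})
        summary = summarize_frequencies(toy_six, spec,
                                        covariates=["q1_smoking_status",
                                                    "q2_item0001"])
        for counts in summary.category_counts.values():
            assert sum(counts.values()) == summary.eligible_n

    def test_idempotent(self, toy_six, toy_six_spec):
        a = summarize_frequencies(toy_six, toy_six_spec).to_dict()
        b = summarize_frequencies(toy_six, toy_six_spec).to_dict()
        assert a == b


class TestEmptyCohort:
    def test_contradictory_criteria_warn_not_error(self, toy_six):
        all_ids = set(toy_six.participants["participant_id"])
        with pytest.warns(UserWarning, match="empty"):
            frame, log = build_cohort_dataset(
                toy_six, make_spec(censoring={"end_of_study": "2010-12-31"}),
                extra_criteria=[("exclude everyone", all_ids)])
        assert len(frame) == 0
        assert log.final_n == 0
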