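"""ICD normalization and matching, SEER site-group recoding, endpoint /
phenotype resolution, and surgery-censoring dates."""

import pytest

from cohortforge import (CancerEndpoint, HospitalPhenotype, MortalityEndpoint,
                         normalize_icd, icd_prefix_match, seer_recode,
                         resolve_cancer_endpoint, resolve_mortality_endpoint,
                         resolve_phenotype, resolve_phenotypes,
                         surgery_censor_dates, endpoint_groups)
from cohortforge.errors import CodeFormatError, SpecificationError

from _oracle import first_qualifying_cancer, rows
from conftest import toy_cancers, toy_hospitalizations


class TestNormalize:
    @pytest.mark.parametrize("raw, canon", [
        ("c50.9", "C509"), (" I21 ", "I21"), ("8500", "8500"), ("C50", "C50"),
    ])
    def test_canonical_form(self, raw, canon):
        assert normalize_icd(raw) == canon

    @pytest.mark.parametrize("bad", ["", "   ", "C50-9", None])
    def test_malformed_rejected(self, bad):
        with pytest.raises(CodeFormatError):
            normalize_icd(bad)

    @pytest.mark.parametrize("code, prefixes, expected", [
        ("C509", {"C50"}, True),
        ("C509", {"C501"}, False),
        ("C50", {"C50"}, True),
        ("I210", {"I21", "I22"}, True),
        ("I210", set(), False),
    ])
    def test_prefix_match(self, code, prefixes, expected):
        assert icd_prefix_match(code, prefixes) is expected


class TestSeerRecode:
    @pytest.mark.parametrize("site, hist, label", [
        ("C50.4", "8500", "Breast"),
        ("C56.9", "8000", "Ovary"),
        ("C99.9", "8000", "other"),
        ("C34.1", "8070", "Lung and Bronchus"),
        ("C54.1", "8380", "Corpus Uteri"),
    ])
    def test_site_ranges(self, site, hist, label):
        assert seer_recode(site, hist) == label

    def test_histology_override_precedes_site(self):
        # lymphoma morphology anywhere recodes to Lymphoma, even in breast
        assert seer_recode("C50.9", "9591") == "Lymphoma"
        assert seer_recode("C18.7", "9823") == "Leukemia"


class TestCancerEndpoint:
    def test_requires_site_or_group(self):
        with pytest.raises(SpecificationError):
            CancerEndpoint()

    def test_include_exclude_must_be_disjoint(self):
        with pytest.raises(SpecificationError):
            CancerEndpoint(site_prefixes={"C50"},
                           histology_include={"8500"}, histology_exclude={"8500"})

    def test_earliest_qualifying_event_wins(self):
        cancers = toy_cancers([
            {"participant_id": "T1", "diagnosis_date": "2003-04-01",
             "sequence_number": "2"},
            {"participant_id": "T1", "diagnosis_date": "2001-09-01",
             "site_code": "C34.1", "histology_code": "8070",
             "seer_group": "Lung and Bronchus", "sequence_number": "1"},
        ])
        out = resolve_cancer_endpoint(cancers, CancerEndpoint(site_prefixes={"C50"}))
        assert out.loc["T1", "diagnosis_date"] == "2003-04-01"

    def test_histology_exclude_removes_only_event(self):
        cancers = toy_cancers([
            {"participant_id": "T1", "diagnosis_date": "2003-04-01",
             "histology_code": "8520"},
        ])
        out = resolve_cancer_endpoint(
            cancers, CancerEndpoint(site_prefixes={"C50"},
                                    histology_exclude={"8520"}))
        assert "T1" not in out.index

    def test_same_day_tie_broken_by_sequence(self):
        cancers = toy_cancers([
            {"participant_id": "T1", "diagnosis_date": "2003-04-01",
             "sequence_number": "2", "site_code": "C50.4"},
            {"participant_id": "T1", "diagnosis_date": "2003-04-01",
             "sequence_number": "1", "site_code": "C50.9"},
        ])
        out = resolve_cancer_endpoint(cancers, CancerEndpoint(site_prefixes={"C50"}))
        assert out.loc["T1", "sequence_number"] == "1"
        assert out.loc["T1", "site_code"] == "C50.9"

    def test_seer_group_matching(self):
        cancers = toy_cancers([
            {"participant_id": "T1", "diagnosis_date": "2003-04-01",
             "site_code": "C56.9", "histology_code": "8441",
             "seer_group": "Ovary"},
        ])
        out = resolve_cancer_endpoint(
            cancers, CancerEndpoint(seer_groups={"Ovary"}))
        assert out.loc["T1", "site_code"] == "C56.9"

    def test_agrees_with_brute_force_scan(self, mid_tables):
        endpoint = CancerEndpoint(site_prefixes={"C50", "C34"},
                                  histology_exclude={"8520"})
        resolved = resolve_cancer_endpoint(mid_tables.cancers, endpoint)
        ep = {"site_prefixes": ["C50", "C34"], "histology_exclude": ["8520"]}
        by_pid = {}
        for row in rows(mid_tables.cancers):
            by_pid.setdefault(row["participant_id"], []).append(row)
        expected = {pid: first_qualifying_cancer(evs, ep)
                    for pid, evs in by_pid.items()}
        expected = {pid: ev for pid, ev in expected.items() if ev is not None}
        assert set(resolved.index) == set(expected)
        for pid, ev in expected.items():
            assert resolved.loc[pid, "diagnosis_date"] == ev["diagnosis_date"]

    def test_widening_prefixes_never_loses_participants(self, mid_tables):
        narrow = resolve_cancer_endpoint(mid_tables.cancers,
                                         CancerEndpoint(site_prefixes={"C50"}))
        wide = resolve_cancer_endpoint(mid_tables.cancers,
                                       CancerEndpoint(site_prefixes={"C50", "C34"}))
        assert set(narrow.index) <= set(wide.index)


class TestMortalityEndpoint:
    def _participants(self):
        from conftest import toy_participants
        return toy_participants([
            {"participant_id": "T1", "vital_status": "dead",
             "date_of_death": "2005-01-01", "cause_of_death": "I21.0"},
            {"participant_id": "T2"},
            {"participant_id": "T3", "vital_status": "dead",
             "date_of_death": "2006-01-01", "cause_of_death": "C50.9"},
        ])

    def test_cause_prefix_match(self):
        out = resolve_mortality_endpoint(self._participants(),
                                         MortalityEndpoint({"I21"}))
        assert list(out.index) == ["T1"]
        assert out.loc["T1", "death_date"] == "2005-01-01"

    def test_alive_participants_never_qualify(self):
        out = resolve_mortality_endpoint(self._participants(),
                                         MortalityEndpoint(frozenset()))
        assert "T2" not in out.index

    def test_empty_prefix_set_is_all_cause(self):
        out = resolve_mortality_endpoint(self._participants(),
                                         MortalityEndpoint(frozenset()))
        assert set(out.index) == {"T1", "T3"}


class TestPhenotype:
    def _hosp(self):
        return toy_hospitalizations([
            {"participant_id": "T1", "admission_date": "2001-03-01",
             "discharge_date": "2001-03-06", "length_of_stay": "5",
             "diagnosis_codes": "I50.9;E11.9"},
            {"participant_id": "T1", "admission_date": "2002-07-01",
             "discharge_date": "2002-07-02", "length_of_stay": "1",
             "diagnosis_codes": "I50.1"},
            {"participant_id": "T2", "admission_date": "2001-05-01",
             "discharge_date": "2001-05-02", "length_of_stay": "1",
             "diagnosis_codes": "E11.9;I50.9"},
        ])

    def test_min_qualifying_admissions_counts_to_nth(self):
        pheno = HospitalPhenotype("hf", frozenset({"I50"}),
                                  min_qualifying_admissions=2)
        out = resolve_phenotype(self._hosp(), pheno)
        assert out.loc["T1", "first_qualifying_date"] == "2002-07-01"
        assert "T2" not in out.index

    def test_length_of_stay_requirement(self):
        pheno = HospitalPhenotype("hf", frozenset({"I50"}), min_length_of_stay=3)
        out = resolve_phenotype(self._hosp(), pheno)
        assert set(out.index) == {"T1"}
        assert out.loc["T1", "first_qualifying_date"] == "2001-03-01"

    def test_principal_only_position_rule(self):
        pheno = HospitalPhenotype("hf", frozenset({"I50"}),
                                  position_rule="principal_only")
        out = resolve_phenotype(self._hosp(), pheno)
        # T2's I50 code is secondary, so only T1 qualifies
        assert set(out.index) == {"T1"}

    def test_multiple_concurrent_phenotypes(self):
        resolved = resolve_phenotypes(self._hosp(), [
            HospitalPhenotype("hf", frozenset({"I50"})),
            HospitalPhenotype("diabetes", frozenset({"E11"})),
        ])
        assert set(resolved) == {"hf", "diabetes"}
        assert set(resolved["diabetes"].index) == {"T1", "T2"}

    def test_duplicate_phenotype_names_rejected(self):
        with pytest.raises(SpecificationError, match="duplicate"):
            resolve_phenotypes(self._hosp(), [
                HospitalPhenotype("hf", frozenset({"I50"})),
                HospitalPhenotype("hf", frozenset({"E11"})),
            ])

    def test_raising_thresholds_never_adds_qualifiers(self, mid_tables):
        hosp = mid_tables.hospitalizations
        base = resolve_phenotype(hosp, HospitalPhenotype("x", frozenset({"I"})))
        for kwargs in ({"min_length_of_stay": 4},
                       {"min_qualifying_admissions": 2}):
            stricter = resolve_phenotype(
                hosp, HospitalPhenotype("x", frozenset({"I"}), **kwargs))
            assert set(stricter.index) <= set(base.index)


class TestSurgeryCensoring:
    def _hosp(self):
        return toy_hospitalizations([
            {"participant_id": "T1", "admission_date": "2003-05-10",
             "discharge_date": "2003-05-13", "length_of_stay": "3",
             "procedure_codes": "85.42"},
            {"participant_id": "T2", "admission_date": "2004-02-01",
             "discharge_date": "2004-02-04", "length_of_stay": "3",
             "procedure_codes": "68.4"},
        ])

    def test_breast_endpoint_uses_mastectomy_date(self):
        out = surgery_censor_dates(self._hosp(), "breast")
        assert out.loc["T1"] == "2003-05-10"
        assert "T2" not in out.index

    def test_organ_specific_codes_do_not_cross(self):
        out = surgery_censor_dates(self._hosp(), "ovary")
        assert len(out) == 0

    def test_none_group_censors_nobody(self):
        out = surgery_censor_dates(self._hosp(), "none")
        assert len(out) == 0

    def test_unknown_group_is_specification_error(self):
        with pytest.raises(SpecificationError):
            surgery_censor_dates(self._hosp(), "pancreas")

    @pytest.mark.parametrize("endpoint, expected", [
        (CancerEndpoint(site_prefixes={"C50"}), {"breast"}),
        (CancerEndpoint(site_prefixes={"C54"}), {"uterus"}),
        (CancerEndpoint(seer_groups={"Ovary"}), {"ovary"}),
        (CancerEndpoint(site_prefixes={"C5"}), {"breast", "uterus", "ovary"}),
        (CancerEndpoint(site_prefixes={"C34"}), set()),
        (MortalityEndpoint(frozenset()), set()),
    ])
    def test_endpoint_group_detection(self, endpoint, expected):
        assert endpoint_groups(endpoint) == frozenset(expected)
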