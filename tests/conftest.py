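from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from cohortforge import SimulationConfig, StudyTables, generate_cohort
from cohortforge.selection import SelectionSpec
from cohortforge.study_model import MISSING_BY_DESIGN, PARTICIPANT_COLUMNS
from cohortforge.synthetic import build_catalog, default_config

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def unit_tables() -> StudyTables:
    return generate_cohort(default_config("unit", seed=1))


@pytest.fixture(scope="session")
def mid_tables() -> StudyTables:
    """1,000 participants with a slim covariate set, for oracle runs."""
    return generate_cohort(SimulationConfig(n_participants=1000,
                                            n_survey_covariates=50, seed=2))


@pytest.fixture(scope="session")
def desk_tables() -> StudyTables:
    return generate_cohort(default_config("desk", seed=11))


def make_spec(endpoint=None, start=None, censoring=None, covariates=None,
              custom_data=None, metadata=None) -> SelectionSpec:
    return SelectionSpec({
        "endpoint": endpoint if endpoint is not None else
        {"type": "cancer", "site_prefixes": ["C50"]},
        "start": start or {"rule": "baseline"},
        "censoring": censoring or {"end_of_study": "2015-12-31"},
        "covariates": covariates if covariates is not None else {"selectors": []},
        "custom_data": custom_data,
        "metadata": metadata or {"project": "test", "design": "cohort"},
    })


@pytest.fixture
def breast_spec() -> SelectionSpec:
    return make_spec()


def _toy_surveys(catalog, participants: pd.DataFrame) -> pd.DataFrame:
    """Survey rows consistent with the participants' wave-date pattern."""
    data = {"participant_id": participants["participant_id"].tolist()}
    for entry in catalog.survey_items():
        values = []
        for _, row in participants.iterrows():
            q = entry.questionnaire_number
            completed = q == 1 or row[f"survey{q}_date"] != ""
            if not completed:
                values.append(MISSING_BY_DESIGN)
            elif entry.name == "q1_height_m":
                values.append("1.60")
            elif entry.name == "q1_weight_kg":
                values.append("64.0")
            elif entry.dtype == "continuous":
                values.append("50.0")
            else:
                values.append(next(iter(entry.value_labels)))
        data[entry.name] = values
    return pd.DataFrame(data, dtype=str)


def toy_participants(rows: list[dict]) -> pd.DataFrame:
    defaults = {c: "" for c in PARTICIPANT_COLUMNS}
    defaults.update({
        "date_of_birth": "1950-06-01", "enrollment_date": "1996-01-15",
        "vital_status": "alive", "race_ethnicity": "1",
        "end_of_linkage": "2012-01-01",
    })
    full = [{**defaults, **r} for r in rows]
    return pd.DataFrame(full, columns=list(PARTICIPANT_COLUMNS), dtype=str)


def toy_cancers(rows: list[dict]) -> pd.DataFrame:
    cols = ["participant_id", "diagnosis_date", "site_code", "histology_code",
            "seer_group", "stage", "grade", "sequence_number"]
    defaults = {"site_code": "C50.9", "histology_code": "8500",
                "seer_group": "Breast", "stage": "2", "grade": "2",
                "sequence_number": "1"}
    full = [{**defaults, **r} for r in rows]
    return pd.DataFrame(full, columns=cols, dtype=str) if full else \
        pd.DataFrame({c: pd.Series(dtype=str) for c in cols})


def toy_hospitalizations(rows: list[dict]) -> pd.DataFrame:
    cols = ["participant_id", "admission_date", "discharge_date",
            "diagnosis_codes", "procedure_codes", "length_of_stay"]
    full = []
    for r in rows:
        row = {"diagnosis_codes": "I10", "procedure_codes": "", **r}
        if "discharge_date" not in row:
            row["discharge_date"] = row["admission_date"]
            row["length_of_stay"] = "0"
        full.append(row)
    return pd.DataFrame(full, columns=cols, dtype=str) if full else \
        pd.DataFrame({c: pd.Series(dtype=str) for c in cols})


def build_toy_tables(participants, cancers=None, hospitalizations=None) -> StudyTables:
    catalog = build_catalog(n_survey_covariates=50, n_followup_surveys=5)
    p = toy_participants(participants)
    return StudyTables(
        participants=p,
        cancers=toy_cancers(cancers or []),
        hospitalizations=toy_hospitalizations(hospitalizations or []),
        surveys=_toy_surveys(catalog, p),
        catalog=catalog,
    )


@pytest.fixture
def toy_six() -> StudyTables:
    """Hand-constructed six-participant fixture covering every exit path:
    one prevalent-cancer exclusion, one other-cancer censor, one event,
    one death, one surgery censor, one administrative censor."""
    return build_toy_tables(
        participants=[
            {"participant_id": "T1"},
            {"participant_id": "T2"},
            {"participant_id": "T3"},
            {"participant_id": "T4", "vital_status": "dead",
             "date_of_death": "2004-07-01", "cause_of_death": "I21.0"},
            {"participant_id": "T5"},
            {"participant_id": "T6"},
        ],
        cancers=[
            {"participant_id": "T1", "diagnosis_date": "1994-05-01"},
            {"participant_id": "T2", "diagnosis_date": "2003-06-15",
             "site_code": "C34.1", "histology_code": "8070",
             "seer_group": "Lung and Bronchus"},
            {"participant_id": "T3", "diagnosis_date": "2005-03-01"},
            {"participant_id": "T5", "diagnosis_date": "2004-01-01"},
        ],
        hospitalizations=[
            {"participant_id": "T5", "admission_date": "2003-05-10",
             "discharge_date": "2003-05-13", "length_of_stay": "3",
             "procedure_codes": "85.42"},
        ],
    )


@pytest.fixture
def toy_six_spec() -> SelectionSpec:
    return make_spec(censoring={"end_of_study": "2010-12-31"})
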