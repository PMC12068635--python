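"""Seeded synthetic prospective-cohort generator.

Emulates the structure of a large women's health cohort: ~133k
participants enrolled over a 1995–1999 window, up to five follow-up
survey waves, ~1200 survey covariates tagged by questionnaire / section /
question, and linked cancer, hospitalization and mortality event
histories.  Event waiting times are exponential with configurable
constant hazards, so closed-form expectations are available for testing;
this is deliberately not a realistic epidemiological model (no age
dependence, no secular trends).

Determinism: output is a pure function of the configuration (which
includes the seed).  Survey covariates are generated in fixed-size
participant chunks, each with its own seed derived from (seed, chunk), so
the in-memory and streamed-to-disk paths produce identical bytes.

Default hazards were chosen so that, at full scale over ~25 years of
follow-up, roughly a quarter of participants develop cancer, a quarter
die, and most are hospitalized at least once — the ballpark the source
cohort reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import Catalog, CatalogEntry, HEIGHT_COLUMN, WEIGHT_COLUMN
from .codes import seer_recode
from .errors import ConfigurationError
from .study_model import (
    CANCER_COLUMNS, HOSPITALIZATION_COLUMNS, PARTICIPANT_COLUMNS,
    MISSING_BY_DESIGN, SURVEY_WAVES, StudyTables, validate_tables, write_table,
)

#: administrative end of the simulated linkage period
SIM_HORIZON = date(2023, 12, 31)

#: participants per survey-generation chunk (fixed: part of determinism)
CHUNK = 16384

#: years after enrollment at which follow-up waves 2..6 are mailed
WAVE_OFFSET_YEARS = (2, 5, 10, 16, 21)
WAVE_RESPONSE_PROB = 0.8
ITEM_NONRESPONSE_PROB = 0.03

_EPOCH_ORD = date(1970, 1, 1).toordinal()

# (ICD-O-3 site, 4-digit morphology, sampling probability)
SITE_POOL = [
    ("C50.9", "8500", 0.20), ("C50.4", "8520", 0.06), ("C34.1", "8070", 0.10),
    ("C18.7", "8140", 0.09), ("C54.1", "8380", 0.08), ("C56.9", "8441", 0.06),
    ("C44.5", "8720", 0.05), ("C77.9", "9591", 0.05), ("C25.9", "8140", 0.05),
    ("C73.9", "8260", 0.05), ("C64.9", "8312", 0.05), ("C67.2", "8120", 0.05),
    ("C53.9", "8070", 0.05), ("C16.9", "8144", 0.06),
]

DX_POOL = ["I21.0", "I50.9", "E11.9", "J44.1", "N39.0",
           "K57.3", "M17.1", "I63.9", "I10", "E78.5"]
GENERIC_PROC_POOL = ["3995", "8154", "4562", "8051"]
# (procedure code, weight): hysterectomy, bilateral oophorectomy variants,
# bilateral mastectomy
SURGERY_PROC_POOL = [("68.4", 0.5), ("65.51", 0.2), ("85.42", 0.15), ("65.61", 0.15)]

CAUSE_POOL = ["C50.9", "C34.9", "I21.0", "I64", "J44.9", "E11.9", "C18.9", "I50.9"]
CAUSE_WEIGHTS = [0.15, 0.12, 0.18, 0.10, 0.12, 0.08, 0.10, 0.15]

SECTIONS = ("demographics", "diet", "physical_activity",
            "medical_history", "medications", "reproductive_health")

MIN_SURVEY_COVARIATES = 50  # 3 named items + 47 generic essential items


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort draw."""
    n_participants: int = 100
    enrollment_window: tuple[date, date] = (date(1995, 10, 27), date(1999, 8, 20))
    n_followup_surveys: int = 5
    n_survey_covariates: int = 1200
    cancer_hazard: float = 0.012          # first primaries per person-year
    hospitalization_rate: float = 0.07    # admissions per person-year
    mortality_hazard: float = 0.013       # deaths per person-year
    surgery_code_fraction: float = 0.05   # P(admission carries an organ-surgery code)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if not (0 <= self.n_followup_surveys <= 5):
            raise ConfigurationError("n_followup_surveys must be in [0, 5]")
        if self.n_survey_covariates < MIN_SURVEY_COVARIATES:
            raise ConfigurationError(
                f"n_survey_covariates must be >= {MIN_SURVEY_COVARIATES}")
        for name in ("cancer_hazard", "hospitalization_rate",
                     "mortality_hazard", "surgery_code_fraction"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.enrollment_window[0] > self.enrollment_window[1]:
            raise ConfigurationError("enrollment window start after end")


PRESETS = {
    "unit": dict(n_participants=100, n_survey_covariates=60),
    "desk": dict(n_participants=10_000, n_survey_covariates=1200),
    "cts_scale": dict(n_participants=133_477, n_survey_covariates=1200,
                      n_followup_surveys=5),
}


def default_config(preset: str, seed: int = 0) -> SimulationConfig:
    """Presets: ``unit`` (n=100), ``desk`` (n=10,000), ``cts_scale``
    (n=133,477 with 1200 survey covariates and five follow-up waves)."""
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}")
    return SimulationConfig(seed=seed, **PRESETS[preset])


# -- catalog -----------------------------------------------------------

def build_catalog(n_survey_covariates: int = 1200,
                  n_followup_surveys: int = 5) -> Catalog:
    """Deterministic synthetic codebook with exactly 62 essential entries:
    11 participant-domain fields, derived BMI, height/weight/smoking, and
    47 generic survey items."""
    entries: list[CatalogEntry] = []

    def participant(name, label, dtype, labels=None, qno=0):
        entries.append(CatalogEntry(
            name=name, label=label, dtype=dtype,
            value_labels=labels or {}, questionnaire_number=1,
            section="participant", question_number=f"P{qno}", essential=True))

    participant("date_of_birth", "Date of birth", "date", qno=1)
    participant("enrollment_date", "Date of baseline survey (enrollment)", "date", qno=2)
    for i, k in enumerate(SURVEY_WAVES, start=3):
        participant(f"survey{k}_date", f"Date follow-up survey {k} completed",
                    "date", qno=i)
    participant("date_of_death", "Date of death", "date", qno=8)
    participant("end_of_linkage", "Last date covered by registry linkage", "date", qno=9)
    participant("vital_status", "Vital status at end of linkage", "categorical",
                {"alive": "Alive", "dead": "Dead", "lost": "Lost to follow-up"}, qno=10)
    participant("race_ethnicity", "Self-reported race/ethnicity", "categorical",
                {str(i): lab for i, lab in enumerate(
                    ["White", "Black", "Hispanic", "Asian/Pacific Islander",
                     "American Indian", "Other/mixed"], start=1)}, qno=11)

    entries.append(CatalogEntry(
        name="bmi", label="Body mass index (kg/m2), derived from self-reported "
        "height and weight", dtype="continuous", derived=True, essential=True))

    entries.append(CatalogEntry(
        name=HEIGHT_COLUMN, label="Self-reported height (m)", dtype="continuous",
        questionnaire_number=1, section="anthropometry", question_number="H1",
        essential=True))
    entries.append(CatalogEntry(
        name=WEIGHT_COLUMN, label="Self-reported weight (kg)", dtype="continuous",
        questionnaire_number=1, section="anthropometry", question_number="H2",
        essential=True))
    entries.append(CatalogEntry(
        name="q1_smoking_status", label="Smoking status", dtype="categorical",
        value_labels={"1": "Never", "2": "Former", "3": "Current"},
        questionnaire_number=1, section="smoking", question_number="S1",
        essential=True))

    n_questionnaires = 1 + n_followup_surveys
    n_generic = n_survey_covariates - 3
    for j in range(n_generic):
        q = (j % n_questionnaires) + 1
        continuous = (j % 3 == 0)
        levels = 2 + (j % 4)
        entries.append(CatalogEntry(
            name=f"q{q}_item{j:04d}",
            label=f"Questionnaire {q} item {j:04d}",
            dtype="continuous" if continuous else "categorical",
            value_labels={} if continuous else
            {str(i): f"Level {i}" for i in range(1, levels + 1)},
            questionnaire_number=q,
            section=SECTIONS[j % len(SECTIONS)],
            question_number=f"Q{j:04d}",
            essential=j < 47,
        ))
    return Catalog(entries)


# -- core event simulation --------------------------------------------

def _ord_to_iso(ordinals: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Vectorized ordinal-day -> ISO string; cells where mask is False -> ""."""
    days = (ordinals - _EPOCH_ORD).astype("int64")
    if mask is not None:
        days = np.where(mask, days, 0)
    iso = days.astype("datetime64[D]").astype("U10").astype(object)
    if mask is not None:
        iso[~mask] = ""
    return iso


def _exponential_days(rng, hazard_per_year: float, size: int) -> np.ndarray:
    if hazard_per_year <= 0:
        return np.full(size, np.inf)
    return rng.exponential(1.0 / hazard_per_year, size) * 365.25


def _simulate_core(config: SimulationConfig):
    """Participants, cancers, hospitalizations and the wave-completion
    matrix; everything except the wide survey table."""
    n = config.n_participants
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    horizon = SIM_HORIZON.toordinal()

    birth = rng.integers(date(1920, 1, 1).toordinal(),
                         date(1975, 12, 31).toordinal() + 1, n)
    w0, w1 = config.enrollment_window
    enroll = rng.integers(w0.toordinal(), w1.toordinal() + 1, n)

    death_delta = _exponential_days(rng, config.mortality_hazard, n)
    finite = np.isfinite(death_delta)
    death = np.full(n, np.iinfo("int64").max)
    death[finite] = enroll[finite] + np.rint(death_delta[finite]).astype("int64")
    dead = death <= horizon
    follow_end = np.minimum(np.where(dead, death, horizon), horizon)

    cause = rng.choice(len(CAUSE_POOL), n, p=np.asarray(CAUSE_WEIGHTS))

    # follow-up waves: mailed at fixed offsets, answered with fixed
    # probability, never after death (missing-by-design)
    n_waves = config.n_followup_surveys
    wave_dates = np.zeros((n, 5), dtype="int64")
    wave_done = np.zeros((n, 5), dtype=bool)
    for i in range(n_waves):
        offset = np.rint(WAVE_OFFSET_YEARS[i] * 365.25).astype("int64")
        jitter = rng.integers(-150, 151, n)
        d = enroll + offset + jitter
        responded = rng.random(n) < WAVE_RESPONSE_PROB
        ok = responded & (d < np.where(dead, death, np.iinfo("int64").max)) & (d <= horizon)
        wave_dates[:, i] = d
        wave_done[:, i] = ok

    # cancer events: first primary at the configured hazard, subsequent
    # primaries rarer (low frequency of multiple primaries)
    event_rows = []
    prev = enroll.astype("float64")
    alive_mask = np.ones(n, dtype=bool)
    for order, factor in enumerate((1.0, 0.3, 0.3), start=1):
        delta = _exponential_days(rng, config.cancer_hazard * factor, n)
        t = prev + delta
        occurs = alive_mask & (t <= follow_end)
        idx = np.flatnonzero(occurs)
        if idx.size:
            site_idx = rng.choice(len(SITE_POOL), idx.size,
                                  p=np.asarray([s[2] for s in SITE_POOL]))
            stage = rng.integers(1, 5, idx.size)
            grade = rng.integers(1, 5, idx.size)
            event_rows.append((idx, np.rint(t[occurs]).astype("int64"),
                               site_idx, stage, grade))
        prev = t
        alive_mask = occurs

    # hospitalizations: Poisson count over each participant's follow-up
    fy = np.maximum(follow_end - enroll, 0) / 365.25
    h_counts = rng.poisson(config.hospitalization_rate * fy)
    h_idx = np.repeat(np.arange(n), h_counts)
    m = h_idx.size
    span = (follow_end[h_idx] - enroll[h_idx] + 1)
    admission = enroll[h_idx] + np.floor(rng.random(m) * span).astype("int64")
    los = rng.poisson(2.5, m)
    los = np.minimum(los, follow_end[h_idx] - admission)  # no post-death stays
    discharge = admission + los

    n_dx = 1 + rng.integers(0, 3, m)
    dx_draws = rng.integers(0, len(DX_POOL), (m, 3))
    has_generic_proc = rng.random(m) < 0.3
    generic_proc = rng.integers(0, len(GENERIC_PROC_POOL), m)
    has_surgery = rng.random(m) < config.surgery_code_fraction
    surgery_proc = rng.choice(len(SURGERY_PROC_POOL), m,
                              p=np.asarray([w for _, w in SURGERY_PROC_POOL]))

    return dict(
        n=n, birth=birth, enroll=enroll, death=death, dead=dead,
        follow_end=follow_end, cause=cause,
        wave_dates=wave_dates, wave_done=wave_done,
        event_rows=event_rows,
        hosp=dict(h_idx=h_idx, admission=admission, discharge=discharge, los=los,
                  n_dx=n_dx, dx_draws=dx_draws, has_generic_proc=has_generic_proc,
                  generic_proc=generic_proc, has_surgery=has_surgery,
                  surgery_proc=surgery_proc),
    )


def _participant_ids(n: int) -> np.ndarray:
    width = max(6, len(str(n)))
    return np.array([f"P{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def _assemble_tables(core: dict, config: SimulationConfig):
    """Build the participants / cancers / hospitalizations string frames."""
    n = core["n"]
    pid = _participant_ids(n)
    dead = core["dead"]

    # cancers
    crow_pid, crow_date, crow_site, crow_hist, crow_stage, crow_grade = \
        [], [], [], [], [], []
    for idx, dates, site_idx, stage, grade in core["event_rows"]:
        crow_pid.append(pid[idx])
        crow_date.append(dates)
        crow_site.append(site_idx)
        crow_stage.append(stage)
        crow_grade.append(grade)
    if crow_pid:
        c_pid = np.concatenate(crow_pid)
        c_date = np.concatenate(crow_date)
        c_site_idx = np.concatenate(crow_site)
        c_stage = np.concatenate(crow_stage)
        c_grade = np.concatenate(crow_grade)
        order = np.lexsort((c_date, c_pid))
        c_pid, c_date = c_pid[order], c_date[order]
        c_site_idx, c_stage, c_grade = c_site_idx[order], c_stage[order], c_grade[order]
        seq = np.ones(c_pid.size, dtype="int64")
        for i in range(1, c_pid.size):
            seq[i] = seq[i - 1] + 1 if c_pid[i] == c_pid[i - 1] else 1
        sites = np.array([SITE_POOL[i][0] for i in c_site_idx], dtype=object)
        hists = np.array([SITE_POOL[i][1] for i in c_site_idx], dtype=object)
        groups = np.array([seer_recode(SITE_POOL[i][0], SITE_POOL[i][1])
                           for i in c_site_idx], dtype=object)
        cancers = pd.DataFrame({
            "participant_id": c_pid,
            "diagnosis_date": _ord_to_iso(c_date),
            "site_code": sites,
            "histology_code": hists,
            "seer_group": groups,
            "stage": c_stage.astype("U1").astype(object),
            "grade": c_grade.astype("U1").astype(object),
            "sequence_number": seq.astype("U2").astype(object),
        }, columns=list(CANCER_COLUMNS))
    else:
        cancers = pd.DataFrame({c: pd.Series(dtype=object) for c in CANCER_COLUMNS})

    # hospitalizations
    h = core["hosp"]
    m = h["h_idx"].size
    dx_strings = np.empty(m, dtype=object)
    proc_strings = np.empty(m, dtype=object)
    for i in range(m):
        k = h["n_dx"][i]
        dx_strings[i] = ";".join(DX_POOL[j] for j in h["dx_draws"][i, :k])
        procs = []
        if h["has_generic_proc"][i]:
            procs.append(GENERIC_PROC_POOL[h["generic_proc"][i]])
        if h["has_surgery"][i]:
            procs.append(SURGERY_PROC_POOL[h["surgery_proc"][i]][0])
        proc_strings[i] = ";".join(procs)
    hospitalizations = pd.DataFrame({
        "participant_id": pid[h["h_idx"]],
        "admission_date": _ord_to_iso(h["admission"]),
        "discharge_date": _ord_to_iso(h["discharge"]),
        "diagnosis_codes": dx_strings,
        "procedure_codes": proc_strings,
        "length_of_stay": h["los"].astype("U4").astype(object),
    }, columns=list(HOSPITALIZATION_COLUMNS))

    # end of linkage: one day past the last observed date, shared by all
    candidates = [core["enroll"].max()]
    if dead.any():
        candidates.append(core["death"][dead].max())
    if core["wave_done"].any():
        candidates.append(core["wave_dates"][core["wave_done"]].max())
    if len(cancers):
        candidates.append(c_date.max())
    if m:
        candidates.append(h["discharge"].max())
    end_of_linkage = date.fromordinal(int(max(candidates))) + timedelta(days=1)

    participants = pd.DataFrame({
        "participant_id": pid,
        "date_of_birth": _ord_to_iso(core["birth"]),
        "enrollment_date": _ord_to_iso(core["enroll"]),
        **{f"survey{k}_date": _ord_to_iso(core["wave_dates"][:, i],
                                          core["wave_done"][:, i])
           for i, k in enumerate(SURVEY_WAVES)},
        "vital_status": np.where(dead, "dead", "alive").astype(object),
        "date_of_death": _ord_to_iso(core["death"], dead),
        "cause_of_death": np.where(
            dead, np.array(CAUSE_POOL, dtype=object)[core["cause"]], "").astype(object),
        "race_ethnicity": (core["birth"] % 6 + 1).astype("U1").astype(object),
        "end_of_linkage": end_of_linkage.isoformat(),
    }, columns=list(PARTICIPANT_COLUMNS))
    return participants, cancers, hospitalizations


# -- survey covariates -------------------------------------------------

_DECI_LOOKUP = np.array([f"{i / 10:.1f}" for i in range(2001)], dtype=object)
_CENTI_LOOKUP = np.array([f"{i / 100:.2f}" for i in range(300)], dtype=object)


def _survey_chunk(entries, completed: np.ndarray, seed: int,
                  chunk_index: int) -> pd.DataFrame:
    """Survey values for one participant chunk.  ``completed`` is the
    (m, 6) questionnaire-completion mask (column 0 = baseline)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7, chunk_index)))
    m = completed.shape[0]
    data: dict[str, np.ndarray] = {}
    for e in entries:
        if e.name == HEIGHT_COLUMN:
            idx = np.clip(np.rint(rng.normal(163, 6.5, m)), 140, 195).astype(int)
            values = _CENTI_LOOKUP[idx]
        elif e.name == WEIGHT_COLUMN:
            idx = np.clip(np.rint(rng.normal(680, 130, m)), 400, 1500).astype(int)
            values = _DECI_LOOKUP[idx]
        elif e.dtype == "continuous":
            idx = np.clip(np.rint(rng.normal(500, 100, m)), 0, 2000).astype(int)
            values = _DECI_LOOKUP[idx]
        else:
            levels = np.array(list(e.value_labels), dtype=object)
            values = levels[rng.integers(0, len(levels), m)]
        values = values.copy()
        done = completed[:, e.questionnaire_number - 1]
        nonresp = rng.random(m) < ITEM_NONRESPONSE_PROB
        values[done & nonresp] = ""
        values[~done] = MISSING_BY_DESIGN
        data[e.name] = values
    return pd.DataFrame(data)


def _iter_survey_chunks(core: dict, catalog: Catalog, config: SimulationConfig):
    n = core["n"]
    pid = _participant_ids(n)
    completed = np.column_stack([np.ones(n, dtype=bool), core["wave_done"]])
    entries = catalog.survey_items()
    for chunk_index, start in enumerate(range(0, n, CHUNK)):
        stop = min(start + CHUNK, n)
        frame = _survey_chunk(entries, completed[start:stop], config.seed, chunk_index)
        frame.insert(0, "participant_id", pid[start:stop])
        yield frame


# -- public API --------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> StudyTables:
    """Draw a full synthetic cohort in memory (unit/desk scale)."""
    catalog = build_catalog(config.n_survey_covariates, config.n_followup_surveys)
    core = _simulate_core(config)
    participants, cancers, hospitalizations = _assemble_tables(core, config)
    surveys = pd.concat(list(_iter_survey_chunks(core, catalog, config)),
                        ignore_index=True)
    return StudyTables(participants, cancers, hospitalizations, surveys, catalog)


def generate_cohort_files(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write the five input CSVs, streaming the wide survey table chunk by
    chunk (full scale never has to fit in memory).  Byte-identical to
    writing :func:`generate_cohort` output."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = build_catalog(config.n_survey_covariates, config.n_followup_surveys)
    core = _simulate_core(config)
    participants, cancers, hospitalizations = _assemble_tables(core, config)
    paths = {
        "participants": write_table(participants, out_dir / "participants.csv"),
        "cancers": write_table(cancers, out_dir / "cancers.csv"),
        "hospitalizations": write_table(hospitalizations,
                                        out_dir / "hospitalizations.csv"),
    }
    survey_path = out_dir / "surveys.csv"
    if survey_path.exists() and not survey_path.stat().st_mode & 0o200:
        raise ConfigurationError(f"{survey_path} is read-only")
    with open(survey_path, "w", encoding="utf-8", newline="") as fh:
        for i, frame in enumerate(_iter_survey_chunks(core, catalog, config)):
            frame.to_csv(fh, index=False, header=(i == 0), lineterminator="\n")
    paths["surveys"] = survey_path
    catalog.write_csv(out_dir / "catalog.csv")
    paths["catalog"] = out_dir / "catalog.csv"
    return paths


# -- deterministic edge-case injection --------------------------------

SCENARIOS = ("same_day_event_death", "prevalent_cancer",
             "surgery_before_diagnosis", "never_responder", "second_primary")


@dataclass(frozen=True)
class ScenarioPatch:
    """A named deterministic edge-case injection for test fixtures."""
    name: str
    participant_id: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIOS}")


def _renumber_cancers(cancers: pd.DataFrame, pid: str) -> pd.DataFrame:
    mask = cancers["participant_id"] == pid
    sub = cancers[mask].sort_values("diagnosis_date", kind="mergesort")
    cancers = cancers.drop(index=sub.index)
    sub = sub.copy()
    sub["sequence_number"] = [str(i) for i in range(1, len(sub) + 1)]
    return pd.concat([cancers, sub], ignore_index=True)


def _add_cancer(tables: StudyTables, pid: str, diagnosis: date,
                site: str, hist: str) -> None:
    row = {
        "participant_id": pid, "diagnosis_date": diagnosis.isoformat(),
        "site_code": site, "histology_code": hist,
        "seer_group": seer_recode(site, hist), "stage": "2", "grade": "2",
        "sequence_number": "0",
    }
    tables.cancers = pd.concat(
        [tables.cancers, pd.DataFrame([row])], ignore_index=True)
    tables.cancers = _renumber_cancers(tables.cancers, pid)


def _pick(tables: StudyTables, predicate) -> str:
    p = tables.participants
    for row in p.itertuples(index=False):
        if predicate(row):
            return row.participant_id
    raise ConfigurationError("no participant satisfies the scenario preconditions")


def inject_scenario(tables: StudyTables, patches: list[ScenarioPatch]) -> StudyTables:
    """Apply named edge-case patches; the result still passes validation.

    A patch that would break a type invariant is rejected with the
    validation report as explanation.
    """
    tables = tables.copy()
    for patch in patches:
        p = tables.participants
        if patch.name == "same_day_event_death":
            pid = patch.participant_id or _pick(tables, lambda r: r.vital_status == "dead")
            dod = p.loc[p["participant_id"] == pid, "date_of_death"].iloc[0]
            _add_cancer(tables, pid, date.fromisoformat(dod), "C50.9", "8500")
        elif patch.name == "prevalent_cancer":
            pid = patch.participant_id or _pick(tables, lambda r: r.vital_status == "alive")
            enroll = date.fromisoformat(
                p.loc[p["participant_id"] == pid, "enrollment_date"].iloc[0])
            _add_cancer(tables, pid, enroll - timedelta(days=400),
                        patch.params.get("site", "C50.9"),
                        patch.params.get("histology", "8500"))
        elif patch.name == "surgery_before_diagnosis":
            cancer_ids = set(tables.cancers["participant_id"])
            pid = patch.participant_id or _pick(
                tables, lambda r: r.vital_status == "alive"
                and r.participant_id not in cancer_ids)
            enroll = date.fromisoformat(
                p.loc[p["participant_id"] == pid, "enrollment_date"].iloc[0])
            surgery_day = enroll + timedelta(days=int(patch.params.get("surgery_offset", 200)))
            row = {
                "participant_id": pid,
                "admission_date": surgery_day.isoformat(),
                "discharge_date": (surgery_day + timedelta(days=3)).isoformat(),
                "diagnosis_codes": "C50.9", "procedure_codes": "85.42",
                "length_of_stay": "3",
            }
            tables.hospitalizations = pd.concat(
                [tables.hospitalizations, pd.DataFrame([row])], ignore_index=True)
            _add_cancer(tables, pid, surgery_day + timedelta(days=240), "C50.9", "8500")
        elif patch.name == "never_responder":
            pid = patch.participant_id or _pick(tables, lambda r: True)
            mask = p["participant_id"] == pid
            for k in SURVEY_WAVES:
                tables.participants.loc[mask, f"survey{k}_date"] = ""
            smask = tables.surveys["participant_id"] == pid
            for e in tables.catalog.survey_items():
                if e.questionnaire_number and e.questionnaire_number > 1 \
                        and e.name in tables.surveys.columns:
                    tables.surveys.loc[smask, e.name] = MISSING_BY_DESIGN
        elif patch.name == "second_primary":
            with_cancer = set(tables.cancers["participant_id"])
            pid = patch.participant_id or _pick(
                tables, lambda r: r.participant_id in with_cancer)
            sub = tables.cancers[tables.cancers["participant_id"] == pid]
            first = date.fromisoformat(sub["diagnosis_date"].min())
            dod = p.loc[p["participant_id"] == pid, "date_of_death"].iloc[0]
            second = first + timedelta(days=600)
            if dod:
                second = min(second, date.fromisoformat(dod))
            _add_cancer(tables, pid, second, "C18.7", "8140")
        report = validate_tables(tables)
        if not report.ok:
            raise ConfigurationError(
                f"scenario {patch.name!r} would violate table invariants:\n{report}")
    return tables
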