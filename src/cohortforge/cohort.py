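"""Cohort construction: start-of-follow-up, eligibility, censoring-rule
resolution, analytic dataset assembly, attrition accounting, and
real-time frequency summaries.

Follow-up runs from the chosen start date to the earliest of: the
qualifying endpoint event, a censoring cancer other than the endpoint,
an organ-removing surgery (automatic for breast / uterus / ovary
endpoints), death, or the administrative end of study.  Same-date ties
are broken by the fixed precedence event > other_cancer > surgery >
death > admin_censor, which favors sensitivity of event capture and
keeps output deterministic.  Person-time is measured in whole days,
``person_days = exit - start``; zero-day follow-up is excluded and
logged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from datetime import date

import numpy as np
import pandas as pd

from ._dates import parse_iso
from .catalog import (CovariateSelector, derive_bmi, select_covariates,
                      HEIGHT_COLUMN, WEIGHT_COLUMN)
from .endpoints import (CancerEndpoint, HospitalPhenotype, MortalityEndpoint,
                        cancer_event_matches, endpoint_groups,
                        resolve_cancer_endpoint, resolve_mortality_endpoint,
                        resolve_phenotypes, surgery_censor_dates)
from .errors import SpecificationError
from .selection import SelectionSpec
from .study_model import MISSING_BY_DESIGN, SURVEY_WAVES, StudyTables

#: same-date tie-break order, most to least preferred
EXIT_PRECEDENCE = ("event", "other_cancer", "surgery", "death", "admin_censor")

_FAR = "9999-12-31"  # sentinel later than any real date


# -- follow-up specification ------------------------------------------

@dataclass(frozen=True)
class StartRule:
    kind: str                      # baseline | survey_k | fixed_date
    k: int | None = None
    date: date | None = None

    def __post_init__(self):
        if self.kind not in ("baseline", "survey_k", "fixed_date"):
            raise SpecificationError(f"unknown start rule {self.kind!r}")
        if self.kind == "survey_k" and self.k not in range(2, 7):
            raise SpecificationError("survey_k start needs k in 2..6")
        if self.kind == "fixed_date" and self.date is None:
            raise SpecificationError("fixed_date start needs a date")


@dataclass(frozen=True)
class FollowupSpec:
    start_rule: StartRule
    end_of_study: date
    censor_other_cancers: bool = True
    auto_surgery_censoring: bool = True
    exclude_prevalent_cancer: bool = True


def parse_endpoint(spec: SelectionSpec):
    """Endpoint section -> typed endpoint object (or phenotype list, or None)."""
    section = spec.endpoint
    if section is None or section["type"] == "none":
        return None
    if section["type"] == "cancer":
        return CancerEndpoint(
            site_prefixes=frozenset(section.get("site_prefixes", [])),
            seer_groups=frozenset(section.get("seer_groups", [])),
            histology_include=frozenset(section.get("histology_include", [])),
            histology_exclude=frozenset(section.get("histology_exclude", [])),
        )
    if section["type"] == "mortality":
        return MortalityEndpoint(frozenset(section.get("cause_prefixes", [])))
    phenos = [HospitalPhenotype(
        name=p["name"],
        diagnosis_prefixes=frozenset(p["diagnosis_prefixes"]),
        min_length_of_stay=int(p.get("min_length_of_stay", 0)),
        min_qualifying_admissions=int(p.get("min_qualifying_admissions", 1)),
        position_rule=p.get("position_rule", "any_listed"),
    ) for p in section.get("phenotypes", [])]
    if not phenos:
        raise SpecificationError("phenotype endpoint section lists no phenotypes")
    return phenos


def parse_followup(spec: SelectionSpec) -> FollowupSpec:
    start = spec.start
    cens = spec.censoring
    if start is None or cens is None:
        raise SpecificationError("spec needs start and censoring sections")
    rule = StartRule(
        kind=start["rule"],
        k=int(start["k"]) if start.get("k") else None,
        date=parse_iso(start["date"]) if start.get("date") else None,
    )
    return FollowupSpec(
        start_rule=rule,
        end_of_study=parse_iso(cens["end_of_study"]),
        censor_other_cancers=bool(cens.get("censor_other_cancers", True)),
        auto_surgery_censoring=bool(cens.get("auto_surgery_censoring", True)),
        exclude_prevalent_cancer=bool(cens.get("exclude_prevalent_cancer", True)),
    )


def parse_selectors(spec: SelectionSpec) -> list[CovariateSelector]:
    section = spec.covariates
    if section is None:
        return []
    return [CovariateSelector.from_dict(d) for d in section.get("selectors", [])]


# -- attrition ---------------------------------------------------------

@dataclass
class AttritionLog:
    """Ordered exclusion accounting from source population to dataset."""
    rows: list[tuple[str, int, int]] = dataclass_field(default_factory=list)

    def append(self, label: str, n_excluded: int, n_remaining: int) -> None:
        if self.rows and n_remaining > self.rows[-1][2]:
            raise SpecificationError("attrition n_remaining may not increase")
        self.rows.append((label, n_excluded, n_remaining))

    @property
    def final_n(self) -> int:
        return self.rows[-1][2]

    @property
    def source_n(self) -> int:
        return self.rows[0][2]

    def total_excluded(self) -> int:
        return sum(r[1] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["criterion", "n_excluded", "n_remaining"])


# -- start of follow-up ------------------------------------------------

def determine_start(participants: pd.DataFrame, rule: StartRule) -> pd.Series:
    """Per-participant start date (ISO string; "" = ineligible)."""
    if rule.kind == "baseline":
        return participants["enrollment_date"].copy()
    if rule.kind == "survey_k":
        return participants[f"survey{rule.k}_date"].copy()
    # fixed calendar date
    d = rule.date.isoformat()
    enroll_min = participants["enrollment_date"].min()
    linkage_max = participants["end_of_linkage"].max()
    if not (enroll_min <= d <= linkage_max):
        raise SpecificationError(
            f"fixed start date {d} outside the enrollment–linkage window "
            f"[{enroll_min}, {linkage_max}]")
    out = pd.Series(d, index=participants.index, dtype=object)
    not_enrolled = participants["enrollment_date"] > d
    dead_before = (participants["date_of_death"] != "") & \
        (participants["date_of_death"] < d)
    past_linkage = participants["end_of_linkage"] < d
    out[not_enrolled | dead_before | past_linkage] = ""
    return out


# -- eligibility -------------------------------------------------------

def apply_eligibility(tables: StudyTables, followup: FollowupSpec,
                      starts: pd.Series,
                      surgery_dates: pd.Series | None = None,
                      extra_criteria=None):
    """Sequential, logged eligibility filtering.

    Steps: valid start of follow-up; alive at start; prevalent-cancer
    exclusion (any cancer diagnosed before start, when enabled); prior
    endpoint-organ surgery (when surgery censoring is active); then any
    user-supplied criteria as (label, excluded-id-set) pairs.  An empty
    cohort is legal and produces a warning, not an error.
    """
    p = tables.participants
    log = AttritionLog()
    log.append("source population", 0, len(p))
    included = pd.Series(True, index=p.index)

    end = followup.end_of_study.isoformat()
    ok_start = (starts != "") & (starts <= end)
    _exclude(log, included, ~ok_start, "no valid start of follow-up")

    dead_at_start = (p["date_of_death"] != "") & (p["date_of_death"] <= starts)
    _exclude(log, included, dead_at_start, "not alive at start of follow-up")

    if followup.exclude_prevalent_cancer:
        first_diag = tables.cancers.groupby("participant_id")["diagnosis_date"].min()
        diag = p["participant_id"].map(first_diag).fillna(_FAR)
        prevalent = diag.values < starts.values
        _exclude(log, included, pd.Series(prevalent, index=p.index),
                 "prevalent cancer at start of follow-up")

    if surgery_dates is not None and len(surgery_dates):
        sdate = p["participant_id"].map(surgery_dates).fillna(_FAR)
        prior = (sdate.values != _FAR) & (sdate.values <= starts.values)
        _exclude(log, included, pd.Series(prior, index=p.index),
                 "prior endpoint-organ surgery")

    for label, excluded_ids in (extra_criteria or []):
        if callable(excluded_ids):
            excluded_ids = excluded_ids(tables)
        mask = p["participant_id"].isin(set(excluded_ids))
        _exclude(log, included, mask, label)

    if not included.any():
        warnings.warn("eligibility criteria exclude every participant; "
                      "the cohort is empty", stacklevel=2)
    return included, log


def _exclude(log: AttritionLog, included: pd.Series, mask: pd.Series,
             label: str) -> None:
    newly = included & mask
    included &= ~mask
    log.append(label, int(newly.sum()), int(included.sum()))


# -- exit resolution ---------------------------------------------------

def resolve_exit(start: str, candidates: list[tuple[str, str]],
                 precedence: tuple[str, ...] = EXIT_PRECEDENCE) -> tuple[str, str]:
    """Earliest candidate (date, status) at or after start; same-date ties
    broken by the fixed precedence.  The administrative candidate must be
    present."""
    live = [(d, s) for d, s in candidates if d >= start]
    if not live:
        raise SpecificationError("no exit candidate on/after start "
                                 "(administrative candidate is mandatory)")
    rank = {s: i for i, s in enumerate(precedence)}
    return min(live, key=lambda c: (c[0], rank[c[1]]))


def _earliest_by_priority(dates: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized resolve_exit: iterate sources in precedence order with a
    strict < comparison so equal dates keep the higher-priority status."""
    n = len(next(iter(dates.values())))
    best_date = np.full(n, "~", dtype=object)   # "~" sorts after any ISO date
    best_status = np.full(n, "", dtype=object)
    for status in EXIT_PRECEDENCE:
        if status not in dates:
            continue
        col = dates[status]
        better = col < best_date
        best_date[better] = col[better]
        best_status[better] = status
    return best_date, best_status


# -- dataset assembly --------------------------------------------------

#: metadata for engine-generated columns (label, dtype, units, value labels)
ENGINE_COLUMNS = {
    "participant_id": ("Universal participant key", "flag", "", {}),
    "start_date": ("Start of follow-up", "date", "", {}),
    "exit_date": ("End of follow-up (event or censoring)", "date", "", {}),
    "status": ("Exit status", "categorical", "",
               {"event": "Endpoint event", "other_cancer": "Censored: other cancer",
                "surgery": "Censored: organ-removing surgery",
                "death": "Censored: death",
                "admin_censor": "Censored: administrative end of study"}),
    "person_days": ("Days of follow-up (exit - start)", "continuous", "days", {}),
    "cause_of_death": ("ICD cause of death", "flag", "", {}),
    "event_date": ("Date of qualifying endpoint event", "date", "", {}),
    "event_site": ("ICD-O-3 site of endpoint event", "flag", "", {}),
    "event_histology": ("ICD-O-3 morphology of endpoint event", "flag", "", {}),
    "event_seer_group": ("SEER site group of endpoint event", "flag", "", {}),
    "event_stage": ("Stage of endpoint event", "flag", "", {}),
    "event_grade": ("Grade of endpoint event", "flag", "", {}),
    "event_cause": ("ICD cause of qualifying death", "flag", "", {}),
    "endpoint_case": ("Endpoint indicator at reference date", "categorical", "",
                      {"0": "No qualifying event", "1": "Qualifying event"}),
}


def _covariate_block(tables: StudyTables, names: list[str],
                     id_order: pd.Series) -> pd.DataFrame:
    """Selected covariate columns, in catalog order, aligned to
    ``id_order``; survey columns carry the missing-by-design marker for
    waves the participant never completed."""
    p = tables.participants.set_index("participant_id")
    p = p.reindex(id_order).fillna("")
    surveys = tables.surveys.set_index("participant_id").reindex(id_order).fillna("")
    wave_absent = {k: (p[f"survey{k}_date"].values == "") for k in SURVEY_WAVES}

    out = {}
    for name in names:
        entry = tables.catalog[name]
        if name in p.columns:                      # participant-domain field
            out[name] = p[name].values
        elif name == "bmi":
            h = surveys[HEIGHT_COLUMN].replace(MISSING_BY_DESIGN, "") \
                if HEIGHT_COLUMN in surveys.columns else pd.Series("", index=surveys.index)
            w = surveys[WEIGHT_COLUMN].replace(MISSING_BY_DESIGN, "") \
                if WEIGHT_COLUMN in surveys.columns else pd.Series("", index=surveys.index)
            bmi = derive_bmi(h, w)
            out[name] = bmi.map(lambda v: "" if pd.isna(v) else f"{v:.1f}").values
        elif entry.is_survey_item:
            values = surveys[name].values.copy()
            q = entry.questionnaire_number
            if q in wave_absent:
                values[wave_absent[q]] = MISSING_BY_DESIGN
            out[name] = values
        else:
            out[name] = np.full(len(id_order), "", dtype=object)
    return pd.DataFrame(out, index=pd.RangeIndex(len(id_order)))


def build_cohort_dataset(tables: StudyTables, spec: SelectionSpec,
                         extra_criteria=None):
    """Apply a complete cohort spec; returns (AnalyticDataset, AttritionLog).

    One row per included participant: identifiers, start/exit/status/
    person_days, endpoint details, the 62 essential covariates plus any
    selected covariates, and phenotype column pairs when defined.
    Deterministic for fixed inputs.
    """
    spec.require_complete()
    endpoint = parse_endpoint(spec)
    followup = parse_followup(spec)
    p = tables.participants
    pid = p["participant_id"]

    starts = determine_start(p, followup.start_rule)

    # endpoint events
    cancer_events = None
    mortality_events = None
    phenotype_tables = {}
    if isinstance(endpoint, CancerEndpoint):
        cancer_events = resolve_cancer_endpoint(tables.cancers, endpoint)
    elif isinstance(endpoint, MortalityEndpoint):
        mortality_events = resolve_mortality_endpoint(p, endpoint)
    elif isinstance(endpoint, list):
        phenotype_tables = resolve_phenotypes(tables.hospitalizations, endpoint)

    # surgery censoring is forced on for breast / uterus / ovary endpoints
    groups = endpoint_groups(endpoint)
    surgery = surgery_censor_dates(tables.hospitalizations, groups) if groups else None

    included, log = apply_eligibility(tables, followup, starts, surgery,
                                      extra_criteria)

    sub = p[included]
    sub_start = starts[included].values
    sub_pid = sub["participant_id"]
    n = len(sub)
    admin = np.minimum(
        np.full(n, followup.end_of_study.isoformat(), dtype=object),
        sub["end_of_linkage"].values.astype(object))

    dates: dict[str, np.ndarray] = {"admin_censor": admin}

    event_date = None
    if cancer_events is not None and len(cancer_events):
        ev = sub_pid.map(cancer_events["diagnosis_date"]).fillna(_FAR).values
        event_date = np.where((ev >= sub_start) & (ev <= admin), ev, _FAR)
        dates["event"] = event_date
    elif mortality_events is not None and len(mortality_events):
        ev = sub_pid.map(mortality_events["death_date"]).fillna(_FAR).values
        event_date = np.where((ev >= sub_start) & (ev <= admin), ev, _FAR)
        dates["event"] = event_date
    elif phenotype_tables:
        lead = endpoint[0].name
        ev = sub_pid.map(
            phenotype_tables[lead]["first_qualifying_date"]).fillna(_FAR).values
        event_date = np.where((ev >= sub_start) & (ev <= admin), ev, _FAR)
        dates["event"] = event_date

    if followup.censor_other_cancers and len(tables.cancers):
        cancers = tables.cancers
        if isinstance(endpoint, CancerEndpoint):
            is_endpoint = np.array([
                cancer_event_matches(s, h, endpoint)
                for s, h in zip(cancers["site_code"], cancers["histology_code"])])
            others = cancers[~is_endpoint]
        else:
            others = cancers
        if len(others):
            start_by_pid = dict(zip(sub_pid, sub_start))
            o = others[others["participant_id"].isin(start_by_pid)]
            o_start = o["participant_id"].map(start_by_pid)
            o = o[o["diagnosis_date"] >= o_start]
            first_other = o.groupby("participant_id")["diagnosis_date"].min()
            dates["other_cancer"] = sub_pid.map(first_other).fillna(_FAR).values

    if surgery is not None and len(surgery):
        dates["surgery"] = sub_pid.map(surgery).fillna(_FAR).values

    death = sub["date_of_death"].values.astype(object)
    dates["death"] = np.where(death == "", _FAR, death)

    exit_date, status = _earliest_by_priority(dates)

    person_days = (
        pd.to_datetime(pd.Series(exit_date)) - pd.to_datetime(pd.Series(sub_start))
    ).dt.days.values

    keep = person_days > 0
    dropped = int((~keep).sum())
    log.append("zero days of follow-up", dropped, int(keep.sum()))

    frame = pd.DataFrame({
        "participant_id": sub_pid.values[keep],
        "start_date": np.asarray(sub_start, dtype=object)[keep],
        "exit_date": exit_date[keep],
        "status": status[keep],
        "person_days": person_days[keep].astype("int64"),
    })

    is_event = frame["status"] == "event"
    if isinstance(endpoint, CancerEndpoint):
        detail = cancer_events.reindex(frame["participant_id"])
        for src, dst in (("diagnosis_date", "event_date"), ("site_code", "event_site"),
                         ("histology_code", "event_histology"),
                         ("seer_group", "event_seer_group"),
                         ("stage", "event_stage"), ("grade", "event_grade")):
            col = detail[src].fillna("").values
            frame[dst] = np.where(is_event, col, "")
    elif isinstance(endpoint, MortalityEndpoint):
        frame["event_date"] = np.where(is_event, frame["exit_date"], "")
        frame["event_cause"] = np.where(
            is_event, frame["participant_id"].map(
                mortality_events["cause"] if mortality_events is not None and
                len(mortality_events) else pd.Series(dtype=object)).fillna(""), "")
    elif isinstance(endpoint, list):
        frame["event_date"] = np.where(is_event, frame["exit_date"], "")
        for pheno in endpoint:
            resolved = phenotype_tables[pheno.name]
            d = frame["participant_id"].map(
                resolved["first_qualifying_date"]).fillna("")
            frame[f"{pheno.name}_case"] = np.where(d != "", "1", "0")
            frame[f"{pheno.name}_first_date"] = d.values

    selected = select_covariates(tables.catalog, parse_selectors(spec))
    block = _covariate_block(tables, selected, frame["participant_id"])
    block = block[[c for c in block.columns if c not in frame.columns]]
    frame = pd.concat([frame.reset_index(drop=True), block], axis=1)

    frame = frame.sort_values("participant_id", kind="mergesort").reset_index(drop=True)
    return frame, log


def build_cross_sectional_dataset(tables: StudyTables, spec: SelectionSpec):
    """Cross-sectional extract at the spec's reference date; returns
    (AnalyticDataset, AttritionLog).

    Rows are participants enrolled on/before and alive at the reference
    date; the endpoint indicator marks a qualifying event on/before it.
    No start/exit/person-time columns.  Without an endpoint section the
    extract is covariate-only.
    """
    meta = spec.metadata or {}
    ref = meta.get("reference_date")
    if not ref:
        raise SpecificationError("cross_sectional design needs metadata.reference_date")
    ref = parse_iso(ref)
    p = tables.participants
    if ref.isoformat() < p["enrollment_date"].min():
        warnings.warn("reference date precedes every enrollment; dataset is empty",
                      stacklevel=2)
    riso = ref.isoformat()

    log = AttritionLog()
    log.append("source population", 0, len(p))
    included = pd.Series(True, index=p.index)
    _exclude(log, included, p["enrollment_date"] > riso,
             "not yet enrolled at reference date")
    _exclude(log, included,
             (p["date_of_death"] != "") & (p["date_of_death"] < riso),
             "dead before reference date")
    _exclude(log, included, p["end_of_linkage"] < riso,
             "linkage ends before reference date")

    sub = p[included]
    frame = pd.DataFrame({"participant_id": sub["participant_id"].values})

    endpoint = parse_endpoint(spec)
    if endpoint is not None:
        if isinstance(endpoint, CancerEndpoint):
            events = resolve_cancer_endpoint(tables.cancers, endpoint)
            ev = frame["participant_id"].map(events["diagnosis_date"]) \
                if len(events) else pd.Series("", index=frame.index)
        elif isinstance(endpoint, MortalityEndpoint):
            events = resolve_mortality_endpoint(p, endpoint)
            ev = frame["participant_id"].map(events["death_date"]) \
                if len(events) else pd.Series("", index=frame.index)
        else:
            resolved = resolve_phenotypes(tables.hospitalizations, endpoint)
            ev = frame["participant_id"].map(
                resolved[endpoint[0].name]["first_qualifying_date"])
        ev = ev.fillna("")
        case = (ev != "") & (ev <= riso)
        frame["endpoint_case"] = np.where(case, "1", "0")
        frame["event_date"] = np.where(case, ev, "")

    selected = select_covariates(tables.catalog, parse_selectors(spec))
    block = _covariate_block(tables, selected, frame["participant_id"])
    block = block[[c for c in block.columns if c not in frame.columns]]
    frame = pd.concat([frame.reset_index(drop=True), block], axis=1)
    frame = frame.sort_values("participant_id", kind="mergesort").reset_index(drop=True)
    return frame, log


# -- frequency summaries ----------------------------------------------

@dataclass
class FrequencySummary:
    """Real-time counts under whatever spec prefix is present."""
    eligible_n: int
    event_n: int | None
    category_counts: dict[str, dict[str, int]]
    endpoint_by_group: dict[str, int]

    def to_dict(self) -> dict:
        return {"eligible_n": self.eligible_n, "event_n": self.event_n,
                "category_counts": self.category_counts,
                "endpoint_by_group": self.endpoint_by_group}


def summarize_frequencies(tables: StudyTables, spec: SelectionSpec,
                          covariates: list[str] | None = None) -> FrequencySummary:
    """Counts under any prefix of a spec: endpoint alone, endpoint+start,
    or the full document.  Categorical counts carry an explicit missing
    bucket; the computation is idempotent."""
    p = tables.participants
    flags = spec.completeness()
    endpoint = parse_endpoint(spec)

    if flags["endpoint"] and flags["start"] and flags["censoring"] \
            and spec.design == "cohort":
        frame, log = build_cohort_dataset(tables, spec)
        eligible_ids = frame["participant_id"]
        eligible_n = len(frame)
        event_n = int((frame["status"] == "event").sum()) if endpoint is not None else None
        group_counts = {}
        if "event_seer_group" in frame.columns:
            vc = frame.loc[frame["status"] == "event", "event_seer_group"] \
                .value_counts()
            group_counts = {str(k): int(v) for k, v in vc.items()}
    else:
        eligible_ids = p["participant_id"]
        eligible_n = len(p)
        event_n = None
        group_counts = {}
        if endpoint is not None:
            if isinstance(endpoint, CancerEndpoint):
                events = resolve_cancer_endpoint(tables.cancers, endpoint)
                event_n = len(events)
                if len(events):
                    vc = events["seer_group"].value_counts()
                    group_counts = {str(k): int(v) for k, v in vc.items()}
            elif isinstance(endpoint, MortalityEndpoint):
                event_n = len(resolve_mortality_endpoint(p, endpoint))
            else:
                resolved = resolve_phenotypes(tables.hospitalizations, endpoint)
                event_n = len(resolved[endpoint[0].name])

    category_counts = {}
    for name in covariates or []:
        entry = tables.catalog[name]
        block = _covariate_block(tables, [name], eligible_ids)
        values = pd.Series(block[name].values)
        values = values.replace({"": "<missing>",
                                 MISSING_BY_DESIGN: "<missing-by-design>"})
        vc = values.value_counts()
        counts = {str(k): int(v) for k, v in vc.items()}
        assert sum(counts.values()) == len(eligible_ids)
        category_counts[entry.name] = counts

    return FrequencySummary(eligible_n, event_n, category_counts, group_counts)
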