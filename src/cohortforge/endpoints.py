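"""Endpoint resolution: cancer endpoints by ICD-O-3 site / SEER site
group / histology, cause-specific or all-cause mortality by ICD prefix,
hospitalization phenotypes by ICD codes with stay and admission-count
requirements, and organ-surgery censoring dates.

All code matching is normalized prefix matching (see :mod:`.codes`).
Resolution is per participant: each resolver returns the earliest
qualifying event, with same-day ties broken deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codes import (
    SeerRecodeMapping, check_surgery_group, default_seer_mapping,
    default_surgery_codes, icd_prefix_match, normalize_icd, normalize_prefixes,
)
from .errors import SpecificationError

POSITION_RULES = ("any_listed", "principal_only")

CANCER_EVENT_FIELDS = ("diagnosis_date", "site_code", "histology_code",
                       "seer_group", "stage", "grade", "sequence_number")


@dataclass(frozen=True)
class CancerEndpoint:
    """Incident-cancer endpoint: ICD-O-3 topography prefixes and/or SEER
    site-group labels, optionally narrowed by morphology codes."""
    site_prefixes: frozenset[str] = frozenset()
    seer_groups: frozenset[str] = frozenset()
    histology_include: frozenset[str] = frozenset()
    histology_exclude: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "site_prefixes", normalize_prefixes(self.site_prefixes))
        object.__setattr__(self, "seer_groups", frozenset(self.seer_groups))
        object.__setattr__(self, "histology_include",
                           normalize_prefixes(self.histology_include))
        object.__setattr__(self, "histology_exclude",
                           normalize_prefixes(self.histology_exclude))
        if not self.site_prefixes and not self.seer_groups:
            raise SpecificationError(
                "cancer endpoint needs site prefixes or SEER site groups")
        if self.histology_include & self.histology_exclude:
            raise SpecificationError(
                "histology include and exclude sets must be disjoint")


@dataclass(frozen=True)
class MortalityEndpoint:
    """ICD cause-of-death prefixes; an empty set means all-cause."""
    cause_prefixes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "cause_prefixes", normalize_prefixes(self.cause_prefixes))


@dataclass(frozen=True)
class HospitalPhenotype:
    """A computable phenotype over hospitalization claims."""
    name: str
    diagnosis_prefixes: frozenset[str]
    min_length_of_stay: int = 0
    min_qualifying_admissions: int = 1
    position_rule: str = "any_listed"

    def __post_init__(self):
        object.__setattr__(self, "diagnosis_prefixes",
                           normalize_prefixes(self.diagnosis_prefixes))
        if not self.name:
            raise SpecificationError("phenotype needs a name")
        if self.min_length_of_stay < 0:
            raise SpecificationError("min_length_of_stay must be >= 0")
        if self.min_qualifying_admissions < 1:
            raise SpecificationError("min_qualifying_admissions must be >= 1")
        if self.position_rule not in POSITION_RULES:
            raise SpecificationError(f"unknown position_rule {self.position_rule!r}")


def cancer_event_matches(site_code: str, histology_code: str,
                         endpoint: CancerEndpoint,
                         mapping: SeerRecodeMapping | None = None) -> bool:
    """(site OR seer-group) AND histology filters, on one event."""
    site = normalize_icd(site_code)
    hist = normalize_icd(histology_code)
    hit = icd_prefix_match(site, endpoint.site_prefixes)
    if not hit and endpoint.seer_groups:
        hit = (mapping or default_seer_mapping()).recode(site_code, histology_code) \
            in endpoint.seer_groups
    if not hit:
        return False
    if endpoint.histology_include and not icd_prefix_match(hist, endpoint.histology_include):
        return False
    if endpoint.histology_exclude and icd_prefix_match(hist, endpoint.histology_exclude):
        return False
    return True


def resolve_cancer_endpoint(cancers: pd.DataFrame, endpoint: CancerEndpoint,
                            mapping: SeerRecodeMapping | None = None) -> pd.DataFrame:
    """Earliest qualifying cancer per participant.

    Same-day ties go to the lowest sequence number.  Returns a frame
    indexed by participant_id with the event fields; participants with no
    qualifying event are absent.
    """
    if not len(cancers):
        return pd.DataFrame(columns=list(CANCER_EVENT_FIELDS))
    mask = [cancer_event_matches(s, h, endpoint, mapping)
            for s, h in zip(cancers["site_code"], cancers["histology_code"])]
    hits = cancers[pd.Series(mask, index=cancers.index)].copy()
    if not len(hits):
        return pd.DataFrame(columns=list(CANCER_EVENT_FIELDS))
    hits["_seq"] = pd.to_numeric(hits["sequence_number"])
    hits = hits.sort_values(["participant_id", "diagnosis_date", "_seq"],
                            kind="mergesort")
    first = hits.groupby("participant_id", sort=True).first()
    return first[list(CANCER_EVENT_FIELDS)]


def resolve_mortality_endpoint(participants: pd.DataFrame,
                               endpoint: MortalityEndpoint) -> pd.DataFrame:
    """Qualifying deaths: dead participants whose cause matches the
    prefixes (all deaths qualify when the prefix set is empty)."""
    dead = participants[participants["vital_status"] == "dead"]
    rows = []
    for row in dead.itertuples(index=False):
        if endpoint.cause_prefixes:
            cause = row.cause_of_death
            if not cause or not icd_prefix_match(normalize_icd(cause),
                                                 endpoint.cause_prefixes):
                continue
        rows.append((row.participant_id, row.date_of_death, row.cause_of_death))
    out = pd.DataFrame(rows, columns=["participant_id", "death_date", "cause"])
    return out.set_index("participant_id")


def _admission_qualifies(diagnosis_codes: str, length_of_stay: str,
                         phenotype: HospitalPhenotype) -> bool:
    codes = [c for c in diagnosis_codes.split(";") if c]
    if phenotype.position_rule == "principal_only":
        codes = codes[:1]
    if not any(icd_prefix_match(normalize_icd(c), phenotype.diagnosis_prefixes)
               for c in codes):
        return False
    los = int(length_of_stay) if length_of_stay else 0
    return los >= phenotype.min_length_of_stay


def resolve_phenotype(hospitalizations: pd.DataFrame,
                      phenotype: HospitalPhenotype) -> pd.DataFrame:
    """Per-participant (indicator, first qualifying date).

    A participant qualifies when their ``min_qualifying_admissions``-th
    qualifying admission occurs; the qualifying date is that admission's
    date.
    """
    mask = [_admission_qualifies(dx, los, phenotype)
            for dx, los in zip(hospitalizations["diagnosis_codes"],
                               hospitalizations["length_of_stay"])]
    hits = hospitalizations[pd.Series(mask, index=hospitalizations.index)]
    hits = hits.sort_values(["participant_id", "admission_date"], kind="mergesort")
    counts = hits.groupby("participant_id").cumcount() + 1
    nth = hits[counts == phenotype.min_qualifying_admissions]
    out = nth.set_index("participant_id")[["admission_date"]]
    out.columns = ["first_qualifying_date"]
    return out


def resolve_phenotypes(hospitalizations: pd.DataFrame,
                       phenotypes: list[HospitalPhenotype]) -> dict[str, pd.DataFrame]:
    """Resolve several concurrent phenotypes; names must be unique."""
    names = [p.name for p in phenotypes]
    if len(set(names)) != len(names):
        raise SpecificationError(f"duplicate phenotype names: {names}")
    return {p.name: resolve_phenotype(hospitalizations, p) for p in phenotypes}


# -- organ-surgery censoring ------------------------------------------

_GROUP_SITE_PREFIXES = {
    "breast": ("C50",),
    "uterus": ("C53", "C54", "C55"),
    "ovary": ("C56",),
}
_GROUP_SEER_LABELS = {
    "breast": {"Breast"},
    "uterus": {"Cervix Uteri", "Corpus Uteri", "Uterus NOS"},
    "ovary": {"Ovary"},
}


def endpoint_groups(endpoint) -> frozenset[str]:
    """Which organ groups (breast / uterus / ovary) a cancer endpoint
    touches; drives automatic surgery censoring."""
    if not isinstance(endpoint, CancerEndpoint):
        return frozenset()
    groups = set()
    for group, sites in _GROUP_SITE_PREFIXES.items():
        for p in endpoint.site_prefixes:
            if any(p.startswith(s) or s.startswith(p) for s in sites):
                groups.add(group)
        if endpoint.seer_groups & _GROUP_SEER_LABELS[group]:
            groups.add(group)
    return frozenset(groups)


def surgery_censor_dates(hospitalizations: pd.DataFrame, endpoint_group,
                         code_sets: dict[str, frozenset[str]] | None = None
                         ) -> pd.Series:
    """Earliest organ-removing surgery per participant for the endpoint
    group(s): bilateral mastectomy (breast), hysterectomy (uterus),
    bilateral oophorectomy (ovary).  ``"none"`` or an empty group set
    yields an empty result."""
    if isinstance(endpoint_group, str):
        check_surgery_group(endpoint_group)
        groups = frozenset() if endpoint_group == "none" else frozenset([endpoint_group])
    else:
        groups = frozenset(check_surgery_group(g) for g in endpoint_group)
    if not groups:
        return pd.Series(dtype=object, name="surgery_date")
    code_sets = code_sets or default_surgery_codes()
    prefixes = frozenset().union(*(code_sets[g] for g in groups))
    mask = []
    for procs in hospitalizations["procedure_codes"]:
        codes = [c for c in procs.split(";") if c]
        mask.append(any(icd_prefix_match(normalize_icd(c), prefixes) for c in codes))
    hits = hospitalizations[pd.Series(mask, index=hospitalizations.index)]
    out = hits.groupby("participant_id")["admission_date"].min()
    out.name = "surgery_date"
    return out
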