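"""Domain tables and the wide presentation table the selection engine queries.

The engine's sole data input is a set of four normalized study tables —
participants, cancer events, hospitalization events, survey responses —
plus the covariate catalog.  All tables are held as string-typed pandas
DataFrames so that CSV serialization round-trips byte-for-byte; empty
cells are plain missing and the reserved sentinel ``".D"`` marks
missing-by-design cells (a survey wave the participant never completed,
e.g. because of death), which is analytically distinct from nonresponse.

:func:`build_presentation_table` materializes the wide, column-oriented
table (one row per participant, participant fields + flattened cancer
events + every survey covariate) that mirrors a warehouse-to-OLAP extract.
"""

from __future__ import annotations

import stat
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

from ._dates import parse_iso
from .catalog import Catalog, derive_bmi, HEIGHT_COLUMN, WEIGHT_COLUMN
from .errors import FormatError, ImmutabilityError, SchemaError

#: reserved sentinel for missing-by-design cells, distinct from plain missing
MISSING_BY_DESIGN = ".D"

SURVEY_WAVES = (2, 3, 4, 5, 6)
SURVEY_DATE_COLUMNS = tuple(f"survey{k}_date" for k in SURVEY_WAVES)

PARTICIPANT_COLUMNS = (
    "participant_id", "date_of_birth", "enrollment_date",
    *SURVEY_DATE_COLUMNS,
    "vital_status", "date_of_death", "cause_of_death",
    "race_ethnicity", "end_of_linkage",
)
CANCER_COLUMNS = (
    "participant_id", "diagnosis_date", "site_code", "histology_code",
    "seer_group", "stage", "grade", "sequence_number",
)
HOSPITALIZATION_COLUMNS = (
    "participant_id", "admission_date", "discharge_date",
    "diagnosis_codes", "procedure_codes", "length_of_stay",
)

VITAL_STATUSES = ("alive", "dead", "lost")

TABLE_FILES = {
    "participants": "participants.csv",
    "cancers": "cancers.csv",
    "hospitalizations": "hospitalizations.csv",
    "surveys": "surveys.csv",
    "catalog": "catalog.csv",
}

CANCER_FLAT_FIELDS = ("diagnosis_date", "site_code", "histology_code",
                      "seer_group", "stage", "grade")


@dataclass
class StudyTables:
    """The four domain tables plus the covariate catalog."""
    participants: pd.DataFrame
    cancers: pd.DataFrame
    hospitalizations: pd.DataFrame
    surveys: pd.DataFrame
    catalog: Catalog

    def copy(self) -> "StudyTables":
        return StudyTables(
            self.participants.copy(), self.cancers.copy(),
            self.hospitalizations.copy(), self.surveys.copy(),
            Catalog(list(self.catalog.entries)),
        )


@dataclass(frozen=True)
class Violation:
    table: str
    participant_id: str
    rule: str
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "all invariants hold"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [{v.table}] {v.participant_id}: {v.rule} — {v.detail}"
                  for v in self.violations]
        return "\n".join(lines)


# -- IO ----------------------------------------------------------------

def read_table(path) -> pd.DataFrame:
    """Read a study CSV with all cells as strings (lossless round-trip)."""
    path = Path(path)
    try:
        if path.suffix == ".parquet":
            frame = pd.read_parquet(path)
            return frame.astype(str)
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path.name}: not valid UTF-8 ({exc})") from exc


def write_table(frame: pd.DataFrame, path) -> Path:
    """Write a table as RFC-4180 CSV (or parquet by suffix).

    Refuses to overwrite a read-only (versioned) file.
    """
    path = Path(path)
    if path.exists() and not (path.stat().st_mode & stat.S_IWUSR):
        raise ImmutabilityError(f"{path} is read-only; versioned data is never overwritten")
    if path.suffix == ".parquet":
        frame.to_parquet(path, index=False)
    else:
        frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    return path


def read_tables(directory) -> StudyTables:
    """Load the five input files (participants, cancers, hospitalizations,
    surveys, catalog) from a directory."""
    directory = Path(directory)
    frames = {}
    for key, fname in TABLE_FILES.items():
        fpath = directory / fname
        if not fpath.exists():
            raise FormatError(f"missing input file {fname} in {directory}")
        frames[key] = read_table(fpath)
    _check_columns(frames["participants"], PARTICIPANT_COLUMNS, "participants.csv")
    _check_columns(frames["cancers"], CANCER_COLUMNS, "cancers.csv")
    _check_columns(frames["hospitalizations"], HOSPITALIZATION_COLUMNS,
                   "hospitalizations.csv")
    if "participant_id" not in frames["surveys"].columns:
        raise SchemaError("surveys.csv must carry the participant_id key column")
    return StudyTables(
        participants=frames["participants"],
        cancers=frames["cancers"],
        hospitalizations=frames["hospitalizations"],
        surveys=frames["surveys"],
        catalog=Catalog.from_frame(frames["catalog"]),
    )


def write_tables(tables: StudyTables, directory) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": write_table(tables.participants, directory / "participants.csv"),
        "cancers": write_table(tables.cancers, directory / "cancers.csv"),
        "hospitalizations": write_table(tables.hospitalizations,
                                        directory / "hospitalizations.csv"),
        "surveys": write_table(tables.surveys, directory / "surveys.csv"),
    }
    tables.catalog.write_csv(directory / "catalog.csv")
    paths["catalog"] = directory / "catalog.csv"
    return paths


def _check_columns(frame: pd.DataFrame, required, fname: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{fname}: missing columns {missing}")


# -- validation --------------------------------------------------------

def _dates_of(series: pd.Series, table: str, rule: str,
              out: list[Violation], ids: pd.Series) -> pd.Series:
    """Parse a date column; unparseable cells become violations + missing."""
    parsed = []
    for pid, value in zip(ids, series):
        try:
            parsed.append(parse_iso(value))
        except FormatError:
            out.append(Violation(table, pid, rule, f"unparseable date {value!r}"))
            parsed.append(None)
    return pd.Series(parsed, index=series.index)


def validate_tables(tables: StudyTables) -> ValidationReport:
    """Check every type invariant; empty report iff all hold."""
    out: list[Violation] = []
    p = tables.participants
    ids = p["participant_id"]

    dupes = ids[ids.duplicated()].unique()
    for pid in dupes:
        out.append(Violation("participants", pid, "unique participant_id",
                             "participant_id appears more than once"))

    dob = _dates_of(p["date_of_birth"], "participants", "valid date_of_birth", out, ids)
    enroll = _dates_of(p["enrollment_date"], "participants", "valid enrollment_date", out, ids)
    death = _dates_of(p["date_of_death"], "participants", "valid date_of_death", out, ids)
    survey_dates = {k: _dates_of(p[f"survey{k}_date"], "participants",
                                 f"valid survey{k}_date", out, ids)
                    for k in SURVEY_WAVES}

    for pid, status, d in zip(ids, p["vital_status"], death):
        if status not in VITAL_STATUSES:
            out.append(Violation("participants", pid, "known vital_status",
                                 f"unknown vital_status {status!r}"))
        if (status == "dead") != (d is not None):
            out.append(Violation("participants", pid, "death date iff dead",
                                 f"vital_status={status!r} but date_of_death "
                                 f"{'present' if d is not None else 'absent'}"))

    for i, pid in zip(p.index, ids):
        e, d = enroll[i], death[i]
        prev: date | None = None
        for k in SURVEY_WAVES:
            s = survey_dates[k][i]
            if s is None:
                continue
            if e is not None and s < e:
                out.append(Violation("participants", pid, "surveys after enrollment",
                                     f"survey{k}_date {s} before enrollment {e}"))
            if prev is not None and s <= prev:
                out.append(Violation("participants", pid, "survey dates strictly increasing",
                                     f"survey{k}_date {s} not after previous survey {prev}"))
            if d is not None and s > d:
                out.append(Violation("participants", pid, "missing-by-design breach",
                                     f"survey{k}_date {s} after date_of_death {d}"))
            prev = s
        if e is not None and d is not None and d < e:
            out.append(Violation("participants", pid, "death after enrollment",
                                 f"date_of_death {d} before enrollment {e}"))

    known = set(ids) - set(dupes)
    dob_by_id = {pid: d for pid, d in zip(ids, dob)}

    c = tables.cancers
    cdiag = _dates_of(c["diagnosis_date"], "cancers", "valid diagnosis_date",
                      out, c["participant_id"])
    for i, pid in zip(c.index, c["participant_id"]):
        if pid not in known:
            out.append(Violation("cancers", pid, "known participant",
                                 "cancer event for unknown participant"))
            continue
        d = cdiag[i]
        b = dob_by_id.get(pid)
        if d is not None and b is not None and d < b:
            out.append(Violation("cancers", pid, "diagnosis after birth",
                                 f"diagnosis_date {d} before date_of_birth {b}"))
    for pid, group in c.groupby("participant_id", sort=False):
        seqs = sorted(pd.to_numeric(group["sequence_number"], errors="coerce").dropna())
        if list(seqs) != list(range(1, len(group) + 1)):
            out.append(Violation("cancers", pid, "contiguous sequence numbers",
                                 f"sequence numbers {seqs} are not 1..{len(group)}"))

    h = tables.hospitalizations
    adm = _dates_of(h["admission_date"], "hospitalizations", "valid admission_date",
                    out, h["participant_id"])
    dis = _dates_of(h["discharge_date"], "hospitalizations", "valid discharge_date",
                    out, h["participant_id"])
    for i, pid in zip(h.index, h["participant_id"]):
        if pid not in known:
            out.append(Violation("hospitalizations", pid, "known participant",
                                 "hospitalization for unknown participant"))
            continue
        a, d = adm[i], dis[i]
        if a is not None and d is not None:
            if d < a:
                out.append(Violation("hospitalizations", pid, "discharge after admission",
                                     f"discharge {d} before admission {a}"))
            los = h["length_of_stay"][i]
            if los != "" and int(los) != (d - a).days:
                out.append(Violation("hospitalizations", pid, "length_of_stay consistent",
                                     f"length_of_stay {los} != discharge-admission "
                                     f"{(d - a).days}"))

    s = tables.surveys
    sdupes = s["participant_id"][s["participant_id"].duplicated()].unique()
    for pid in sdupes:
        out.append(Violation("surveys", pid, "one survey row per participant",
                             "participant_id appears more than once"))
    for pid in set(s["participant_id"]) - known:
        out.append(Violation("surveys", pid, "known participant",
                             "survey row for unknown participant"))

    return ValidationReport(out)


# -- presentation table ------------------------------------------------

def flatten_cancers(cancers: pd.DataFrame, participant_ids: pd.Series,
                    k_primaries: int = 3) -> pd.DataFrame:
    """One row per participant; the first ``k_primaries`` cancers by
    sequence number become ``cancer{i}_*`` column blocks (empty for
    cancer-free participants)."""
    ordered = cancers.copy()
    ordered["_seq"] = pd.to_numeric(ordered["sequence_number"], errors="coerce")
    ordered = ordered.sort_values(["participant_id", "_seq"], kind="mergesort")
    ordered["_rank"] = ordered.groupby("participant_id").cumcount() + 1
    ordered = ordered[ordered["_rank"] <= k_primaries]

    out = pd.DataFrame({"participant_id": participant_ids.values})
    for i in range(1, k_primaries + 1):
        block = ordered[ordered["_rank"] == i].set_index("participant_id")
        for fieldname in CANCER_FLAT_FIELDS:
            col = out["participant_id"].map(block[fieldname]).fillna("")
            out[f"cancer{i}_{fieldname}"] = col
    return out


def build_presentation_table(tables: StudyTables, k_primaries: int = 3) -> pd.DataFrame:
    """Assemble the wide cohort table: participant fields, flattened cancer
    events, derived BMI, and every cataloged survey covariate, with
    missing-by-design markers enforced from the survey-date pattern."""
    p = tables.participants
    survey_cols = [e.name for e in tables.catalog.survey_items()]
    absent = [c for c in survey_cols if c not in tables.surveys.columns]
    if absent:
        raise SchemaError(f"catalog names columns absent from the survey table: {absent[:5]}"
                          + ("..." if len(absent) > 5 else ""))

    wide = p.copy()
    cancer_flat = flatten_cancers(tables.cancers, p["participant_id"], k_primaries)
    wide = wide.merge(cancer_flat, on="participant_id", how="left")

    surveys = tables.surveys.set_index("participant_id")
    block = surveys.reindex(wide["participant_id"])[survey_cols].reset_index(drop=True)

    # enforce missing-by-design closure: wave-k columns carry the marker
    # exactly when survey k was never completed
    wave_absent = {k: (p[f"survey{k}_date"].values == "") for k in SURVEY_WAVES}
    for entry in tables.catalog.survey_items():
        q = entry.questionnaire_number
        if q in wave_absent:
            col = block[entry.name].values.copy()
            col[wave_absent[q]] = MISSING_BY_DESIGN
            col[~wave_absent[q] & (col == MISSING_BY_DESIGN)] = ""
            block[entry.name] = col

    if "bmi" in tables.catalog and HEIGHT_COLUMN in block and WEIGHT_COLUMN in block:
        bmi = derive_bmi(block[HEIGHT_COLUMN].replace(MISSING_BY_DESIGN, ""),
                         block[WEIGHT_COLUMN].replace(MISSING_BY_DESIGN, ""))
        wide["bmi"] = bmi.round(1).map(lambda v: "" if pd.isna(v) else f"{v:.1f}")

    for colname in survey_cols:
        wide[colname] = block[colname].values
    return wide
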