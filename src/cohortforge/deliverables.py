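"""One-shot generation of the six run deliverables.

Every completed run emits: (1) the analytic CSV dataset, (2) a formats
file with the value-label definitions for the commercial dialect, (3) a
commercial-package (SAS-style) data-call script, (4) an open-source (R)
reader script, (5) a custom data dictionary covering exactly the dataset
columns, and (6) a human-readable selection summary.  The dataset and
formats file are routed to a read-only data directory; the scripts,
dictionary and summary to the project directory.  Versions are
monotonically increasing integers per project; prior versions are never
mutated, and every file carries a SHA-256 checksum in the manifest.

Deliverables are byte-identical for identical inputs, except the
summary's generation-timestamp line.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import stat
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .catalog import Catalog, format_value_labels
from .cohort import ENGINE_COLUMNS, AttritionLog
from .errors import (CompletenessError, ImmutabilityError, JoinError,
                     SpecificationError)
from .selection import SelectionSpec

READER_DIALECTS = ("sas", "r")

ROLES = ("dataset", "formats", "reader_sas", "reader_r", "dictionary", "summary")

_ROLE_FILES = {
    "dataset": ("data", "dataset.csv"),
    "formats": ("data", "formats.sas"),
    "reader_sas": ("project", "read_data.sas"),
    "reader_r": ("project", "read_data.R"),
    "dictionary": ("project", "dictionary.csv"),
    "summary": ("project", "summary.md"),
}


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class DeliverableEntry:
    role: str
    directory: str        # "data" or "project"
    relpath: str
    checksum: str
    read_only: bool


@dataclass
class DeliverableManifest:
    project: str
    version_id: int
    entries: list[DeliverableEntry]
    data_dir: Path
    project_dir: Path

    def path(self, role: str) -> Path:
        entry = next(e for e in self.entries if e.role == role)
        base = self.data_dir if entry.directory == "data" else self.project_dir
        return base / entry.relpath

    def checksum(self, role: str) -> str:
        return next(e.checksum for e in self.entries if e.role == role)

    def to_dict(self) -> dict:
        return {
            "project": self.project,
            "version_id": self.version_id,
            "entries": [{"role": e.role, "directory": e.directory,
                         "relpath": e.relpath, "checksum": e.checksum,
                         "read_only": e.read_only} for e in self.entries],
        }

    def save(self, path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")
        return Path(path)

    @classmethod
    def load(cls, path, data_dir, project_dir) -> "DeliverableManifest":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            project=raw["project"], version_id=raw["version_id"],
            entries=[DeliverableEntry(**e) for e in raw["entries"]],
            data_dir=Path(data_dir), project_dir=Path(project_dir),
        )

    def verify(self) -> list[str]:
        """Recompute checksums; returns a report line per mismatch."""
        problems = []
        for e in self.entries:
            p = self.path(e.role)
            if not p.exists():
                problems.append(f"{e.role}: missing file {p}")
            elif sha256_file(p) != e.checksum:
                problems.append(f"{e.role}: checksum mismatch for {p}")
        return problems


# -- individual renderers ---------------------------------------------

def _column_metadata(name: str, catalog: Catalog) -> dict:
    if name in catalog:
        e = catalog[name]
        source = "derived" if e.derived else (
            "participant" if e.section == "participant"
            else f"questionnaire {e.questionnaire_number}")
        return {"label": e.label, "dtype": e.dtype,
                "value_labels": format_value_labels(e.value_labels),
                "source": source, "units": ""}
    if name in ENGINE_COLUMNS:
        label, dtype, units, labels = ENGINE_COLUMNS[name]
        return {"label": label, "dtype": dtype,
                "value_labels": format_value_labels(labels),
                "source": "engine", "units": units}
    if name.endswith("_case"):
        pheno = name[:-5]
        return {"label": f"Phenotype indicator: {pheno}", "dtype": "categorical",
                "value_labels": "0=No|1=Yes", "source": "engine", "units": ""}
    if name.endswith("_first_date"):
        pheno = name[:-11]
        return {"label": f"First qualifying admission date: {pheno}",
                "dtype": "date", "value_labels": "", "source": "engine", "units": ""}
    raise CompletenessError(f"dataset column {name!r} has no dictionary metadata")


def render_dictionary(catalog: Catalog, columns: list[str],
                      version_id: int) -> pd.DataFrame:
    """One entry per dataset column, none extra (dictionary-dataset
    bijection); covariates not selected never appear."""
    rows = []
    for name in columns:
        meta = _column_metadata(name, catalog)
        rows.append({"name": name, **meta, "version_id": str(version_id)})
    return pd.DataFrame(rows, columns=["name", "label", "dtype", "value_labels",
                                       "source", "units", "version_id"])


def render_formats_file(catalog: Catalog, columns: list[str]) -> str:
    """Value-label format blocks for every categorical dataset column.

    Grammar (bit-exact): ``proc format;`` then per column
    ``value <NAME>F <code>='<label>' ... ;`` then ``run;``.  Quotes in
    labels are doubled.
    """
    lines = ["proc format;"]
    for name in columns:
        meta = _column_metadata(name, catalog)
        if meta["dtype"] != "categorical" or not meta["value_labels"]:
            continue
        lines.append(f"  value {name.upper()}F")
        for pair in meta["value_labels"].split("|"):
            code, _, label = pair.partition("=")
            label = label.replace("'", "''")
            lines.append(f"    {code}='{label}'")
        lines.append("  ;")
    lines.append("run;")
    return "\n".join(lines) + "\n"


def _sas_name(name: str) -> str:
    return name.upper()


def render_reader_script(dialect: str, dataset_relpath: str,
                         formats_relpath: str, catalog: Catalog,
                         columns: list[str], version_id: int) -> str:
    """A data-call script that reads the versioned CSV and declares every
    column exactly once with its type; the commercial dialect applies
    value labels via the formats file, the open-source dialect inline."""
    if dialect not in READER_DIALECTS:
        raise SpecificationError(
            f"unknown reader dialect {dialect!r}; expected one of {READER_DIALECTS}")
    metas = {name: _column_metadata(name, catalog) for name in columns}
    if dialect == "sas":
        lines = [
            f"/* Data call for version {version_id}; generated by cohortforge.",
            "   Paths resolve against the read-only data root. */",
            f"%include '{formats_relpath}';",
            "data analytic;",
            f"  infile '{dataset_relpath}' dsd dlm=',' firstobs=2 truncover;",
            "  input",
        ]
        for name in columns:
            dtype = metas[name]["dtype"]
            char = dtype in ("flag",) or name == "participant_id"
            suffix = " :$64." if char else (" :yymmdd10." if dtype == "date" else "")
            lines.append(f"    {_sas_name(name)}{suffix}")
        lines.append("  ;")
        for name in columns:
            if metas[name]["dtype"] == "date":
                lines.append(f"  format {_sas_name(name)} yymmdd10.;")
        for name in columns:
            if metas[name]["dtype"] == "categorical" and metas[name]["value_labels"]:
                lines.append(f"  format {_sas_name(name)} {_sas_name(name)}F.;")
        lines.append("run;")
        return "\n".join(lines) + "\n"

    lines = [
        f"# Reader for version {version_id}; generated by cohortforge.",
        "# Paths resolve against the read-only data root.",
        f'dataset_path <- "{dataset_relpath}"',
        'missing_by_design <- ".D"',
        "col_classes <- c(",
    ]
    class_map = {"categorical": "character", "continuous": "numeric",
                 "date": "character", "flag": "character"}
    decls = [f'  {name} = "{class_map[metas[name]["dtype"]]}"' for name in columns]
    lines.append(",\n".join(decls))
    lines += [
        ")",
        "analytic <- read.csv(dataset_path, colClasses = col_classes,",
        '                     na.strings = c(""), check.names = FALSE)',
    ]
    for name in columns:
        meta = metas[name]
        if meta["dtype"] == "date":
            lines.append(f'analytic${name} <- as.Date(analytic${name})')
        elif meta["dtype"] == "categorical" and meta["value_labels"]:
            codes, labels = [], []
            for pair in meta["value_labels"].split("|"):
                code, _, label = pair.partition("=")
                codes.append(f'"{code}"')
                labels.append('"' + label.replace('"', '\\"') + '"')
            lines.append(
                f'analytic${name} <- factor(analytic${name}, '
                f'levels = c({", ".join(codes)}), labels = c({", ".join(labels)}))')
    return "\n".join(lines) + "\n"


def render_summary(spec: SelectionSpec, attrition: AttritionLog,
                   version_id: int, project: str,
                   timestamp: datetime | None = None) -> str:
    """Human-readable restatement of every selection choice plus the
    attrition table.  The timestamp line is excluded from determinism
    checks."""
    ts = (timestamp or datetime.now(timezone.utc)).isoformat(timespec="seconds")
    lines = [f"# Selection summary — {project}, version {version_id}",
             "", f"generated: {ts}", ""]

    ep = spec.endpoint
    lines.append("## Endpoint")
    if ep is None or ep["type"] == "none":
        lines.append("- none (covariate-only extract)")
    elif ep["type"] == "cancer":
        lines.append(f"- cancer endpoint; ICD-O-3 site prefixes: "
                     f"{sorted(ep.get('site_prefixes', [])) or '—'}; "
                     f"SEER site groups: {sorted(ep.get('seer_groups', [])) or '—'}")
        if ep.get("histology_include"):
            lines.append(f"- histology include: {sorted(ep['histology_include'])}")
        if ep.get("histology_exclude"):
            lines.append(f"- histology exclude: {sorted(ep['histology_exclude'])}")
    elif ep["type"] == "mortality":
        causes = sorted(ep.get("cause_prefixes", []))
        lines.append(f"- mortality endpoint; cause prefixes: {causes or 'all causes'}")
    else:
        for p in ep.get("phenotypes", []):
            lines.append(
                f"- phenotype {p['name']}: ICD prefixes {sorted(p['diagnosis_prefixes'])}, "
                f"min stay {p.get('min_length_of_stay', 0)} d, "
                f"min admissions {p.get('min_qualifying_admissions', 1)}, "
                f"position {p.get('position_rule', 'any_listed')}")

    lines.append("")
    lines.append("## Start of follow-up")
    st = spec.start
    if st is None:
        lines.append("- (not set)")
    elif st["rule"] == "baseline":
        lines.append("- baseline survey (enrollment date)")
    elif st["rule"] == "survey_k":
        lines.append(f"- follow-up survey {st['k']} completion date")
    else:
        lines.append(f"- fixed date {st['date']}")

    lines.append("")
    lines.append("## Censoring and exclusions")
    cen = spec.censoring or {}
    yn = lambda v: "yes" if v else "no"
    lines.append(f"- end of study: {cen.get('end_of_study', '(not set)')}")
    lines.append(f"- censor other cancers: {yn(cen.get('censor_other_cancers', True))}")
    lines.append(f"- automatic organ-surgery censoring: "
                 f"{yn(cen.get('auto_surgery_censoring', True))}")
    lines.append(f"- prevalent cancer excluded: "
                 f"{yn(cen.get('exclude_prevalent_cancer', True))}")

    lines.append("")
    lines.append("## Covariate selectors")
    cov = spec.covariates or {}
    selectors = cov.get("selectors", [])
    if selectors:
        for sel in selectors:
            kind, value = next(iter(sel.items()))
            lines.append(f"- {kind}: {value}")
    else:
        lines.append("- essential covariate set only")

    lines.append("")
    lines.append("## Attrition")
    lines.append("| criterion | excluded | remaining |")
    lines.append("|---|---|---|")
    for label, excl, rem in attrition.rows:
        lines.append(f"| {label} | {excl} | {rem} |")
    lines.append("")
    return "\n".join(lines)


# -- orchestration -----------------------------------------------------

def _next_version(*dirs: Path) -> int:
    latest = 0
    for d in dirs:
        if d.exists():
            for child in d.iterdir():
                if child.is_dir() and child.name.startswith("v") \
                        and child.name[1:].isdigit():
                    latest = max(latest, int(child.name[1:]))
    return latest + 1


def _make_read_only(path: Path) -> None:
    path.chmod(stat.S_IRUSR | stat.S_IRGRP | stat.S_IROTH)


def generate_deliverables(dataset: pd.DataFrame, spec: SelectionSpec,
                          catalog: Catalog, attrition: AttritionLog,
                          project_dir, data_dir,
                          timestamp: datetime | None = None) -> DeliverableManifest:
    """Write all six deliverables for one completed run.

    The dataset and formats file land under ``data_dir/<project>/v<N>``
    (made read-only); scripts, dictionary and summary under
    ``project_dir/<project>/v<N>``.  ``version_id`` is the previous
    maximum plus one; existing versions are never touched.  On any
    failure, partially written files are rolled back and no manifest is
    produced.
    """
    project = spec.project
    data_root = Path(data_dir) / project
    project_root = Path(project_dir) / project
    version = _next_version(data_root, project_root)
    data_ver = data_root / f"v{version}"
    project_ver = project_root / f"v{version}"

    data_root.mkdir(parents=True, exist_ok=True)
    project_root.mkdir(parents=True, exist_ok=True)
    try:
        data_ver.mkdir(exist_ok=False)
        project_ver.mkdir(exist_ok=False)
    except FileExistsError as exc:
        raise ImmutabilityError(f"version v{version} already exists; "
                                "existing versions are never overwritten") from exc

    columns = list(dataset.columns)
    dataset_path = data_ver / "dataset.csv"
    formats_path = data_ver / "formats.sas"
    try:
        dataset.to_csv(dataset_path, index=False, lineterminator="\n",
                       encoding="utf-8")
        formats_path.write_text(render_formats_file(catalog, columns),
                                encoding="utf-8")

        # scripts reference the versioned relative path (resolved against
        # the read-only data root), keeping deliverables byte-identical
        # for identical inputs wherever the directories live
        rel_dataset = str(Path(project) / f"v{version}" / "dataset.csv")
        rel_formats = str(Path(project) / f"v{version}" / "formats.sas")

        (project_ver / "read_data.sas").write_text(
            render_reader_script("sas", rel_dataset, rel_formats, catalog,
                                 columns, version), encoding="utf-8")
        (project_ver / "read_data.R").write_text(
            render_reader_script("r", rel_dataset, rel_formats, catalog,
                                 columns, version), encoding="utf-8")
        dictionary = render_dictionary(catalog, columns, version)
        dictionary.to_csv(project_ver / "dictionary.csv", index=False,
                          lineterminator="\n", encoding="utf-8")
        (project_ver / "summary.md").write_text(
            render_summary(spec, attrition, version, project, timestamp),
            encoding="utf-8")

        entries = []
        for role, (which, fname) in _ROLE_FILES.items():
            base = data_ver if which == "data" else project_ver
            path = base / fname
            entries.append(DeliverableEntry(
                role=role, directory=which,
                relpath=str(Path(project) / f"v{version}" / fname),
                checksum=sha256_file(path), read_only=(which == "data")))
        _make_read_only(dataset_path)
        _make_read_only(formats_path)

        manifest = DeliverableManifest(project=project, version_id=version,
                                       entries=entries,
                                       data_dir=Path(data_dir),
                                       project_dir=Path(project_dir))
        manifest.save(project_ver / "manifest.json")
        return manifest
    except Exception:
        for path in (dataset_path, formats_path):
            if path.exists():
                path.chmod(0o644)
        shutil.rmtree(data_ver, ignore_errors=True)
        shutil.rmtree(project_ver, ignore_errors=True)
        raise


def list_versions(project_dir, project: str) -> list[int]:
    root = Path(project_dir) / project
    if not root.exists():
        return []
    return sorted(int(c.name[1:]) for c in root.iterdir()
                  if c.is_dir() and c.name.startswith("v") and c.name[1:].isdigit())


# -- custom-data joins -------------------------------------------------

def emit_custom_join(excerpt_path, manifest: DeliverableManifest):
    """Generate a left-join script for a custom-data excerpt and validate
    its universal key.

    The excerpt must carry ``participant_id``; the report flags excerpt
    keys absent from the dataset and duplicated keys.  The join is a left
    join onto the versioned dataset, so the dataset row count is
    preserved.
    """
    excerpt_path = Path(excerpt_path)
    excerpt = pd.read_csv(excerpt_path, dtype=str, keep_default_na=False)
    if "participant_id" not in excerpt.columns:
        raise JoinError(f"{excerpt_path.name}: missing universal key column "
                        "participant_id")
    dataset = pd.read_csv(manifest.path("dataset"), dtype=str,
                          keep_default_na=False, usecols=["participant_id"])
    dataset_ids = set(dataset["participant_id"])
    excerpt_ids = list(excerpt["participant_id"])
    report = {
        "excerpt_rows": len(excerpt),
        "keys_not_in_dataset": sorted(set(excerpt_ids) - dataset_ids),
        "duplicate_keys": sorted({k for k in excerpt_ids
                                  if excerpt_ids.count(k) > 1}),
    }
    script = "\n".join([
        f"# Join custom excerpt {excerpt_path.name} onto dataset version "
        f"{manifest.version_id} (left join on the universal key).",
        f'dataset <- read.csv("{manifest.path("dataset")}", colClasses = "character")',
        f'excerpt <- read.csv("{excerpt_path}", colClasses = "character")',
        'joined <- merge(dataset, excerpt, by = "participant_id", '
        "all.x = TRUE, sort = TRUE)",
        "stopifnot(nrow(joined) >= nrow(dataset))",
    ]) + "\n"
    out_path = manifest.path("summary").parent / f"join_{excerpt_path.stem}.R"
    out_path.write_text(script, encoding="utf-8")
    return out_path, report
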