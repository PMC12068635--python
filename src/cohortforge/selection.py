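"""The declarative selection specification.

A :class:`SelectionSpec` captures every researcher choice in six sections
mirroring the selection wizard's steps:

1. ``endpoint``    — cancer / mortality / phenotype list / none
2. ``start``       — start-of-follow-up rule
3. ``censoring``   — end of study, other-cancer / surgery censoring,
                     prevalent-cancer exclusion
4. ``covariates``  — covariate selectors
5. ``custom_data`` — expected custom-excerpt schemas
6. ``metadata``    — project slug, design, reference date

Specs are immutable: :meth:`SelectionSpec.revise` returns a new document
with exactly one section replaced.  Files are JSON or YAML; user-entered
``MM/DD/YYYY`` dates are normalized to ISO on load and save.  Partial
specs are legal (interim progress) and load with per-section completeness
flags.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from ._dates import parse_user_date
from .errors import FormatError, MigrationError, SpecificationError

SCHEMA_VERSION = 1

SECTIONS = ("endpoint", "start", "censoring", "covariates", "custom_data", "metadata")

ENDPOINT_TYPES = ("cancer", "mortality", "phenotypes", "none")
START_RULES = ("baseline", "survey_k", "fixed_date")
DESIGNS = ("cohort", "cross_sectional")

_DATE_FIELDS = {
    "start": ("date",),
    "censoring": ("end_of_study",),
    "metadata": ("reference_date",),
}


def _normalize_dates(section: str, content: dict) -> dict:
    for fieldname in _DATE_FIELDS.get(section, ()):
        value = content.get(fieldname)
        if value:
            content[fieldname] = parse_user_date(str(value)).isoformat()
    return content


def _check_section(section: str, content) -> None:
    if content is None:
        return
    if not isinstance(content, dict):
        raise SpecificationError(f"section {section!r} must be a mapping")
    if section == "endpoint":
        etype = content.get("type")
        if etype not in ENDPOINT_TYPES:
            raise SpecificationError(
                f"endpoint.type must be one of {ENDPOINT_TYPES}, got {etype!r}")
    elif section == "start":
        rule = content.get("rule")
        if rule not in START_RULES:
            raise SpecificationError(
                f"start.rule must be one of {START_RULES}, got {rule!r}")
        if rule == "survey_k" and int(content.get("k", 0)) not in range(2, 7):
            raise SpecificationError("start.k must be in 2..6 for survey_k")
        if rule == "fixed_date" and not content.get("date"):
            raise SpecificationError("start.date is required for fixed_date")
    elif section == "censoring":
        if not content.get("end_of_study"):
            raise SpecificationError("censoring.end_of_study is required")
    elif section == "covariates":
        if not isinstance(content.get("selectors", []), list):
            raise SpecificationError("covariates.selectors must be a list")
    elif section == "metadata":
        design = content.get("design", "cohort")
        if design not in DESIGNS:
            raise SpecificationError(f"metadata.design must be one of {DESIGNS}")
        if design == "cross_sectional" and not content.get("reference_date"):
            raise SpecificationError(
                "cross_sectional design needs metadata.reference_date")


class SelectionSpec:
    """Immutable six-section selection document."""

    def __init__(self, data: dict):
        unknown = set(data) - set(SECTIONS) - {"schema_version"}
        if unknown:
            raise SpecificationError(f"unknown spec sections: {sorted(unknown)}")
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise MigrationError(
                f"spec schema version {version} is not supported; this engine "
                f"reads version {SCHEMA_VERSION}")
        self._data = {}
        for section in SECTIONS:
            content = copy.deepcopy(data.get(section))
            if isinstance(content, dict):
                content = _normalize_dates(section, content)
            _check_section(section, content)
            self._data[section] = content

    # -- access --------------------------------------------------------
    def section(self, name: str):
        if name not in SECTIONS:
            raise SpecificationError(f"unknown section {name!r}")
        return copy.deepcopy(self._data[name])

    @property
    def endpoint(self):
        return self._data["endpoint"]

    @property
    def start(self):
        return self._data["start"]

    @property
    def censoring(self):
        return self._data["censoring"]

    @property
    def covariates(self):
        return self._data["covariates"]

    @property
    def custom_data(self):
        return self._data["custom_data"]

    @property
    def metadata(self):
        return self._data["metadata"]

    @property
    def design(self) -> str:
        meta = self._data["metadata"] or {}
        return meta.get("design", "cohort")

    @property
    def project(self) -> str:
        meta = self._data["metadata"] or {}
        return meta.get("project", "project")

    def to_dict(self) -> dict:
        out = {"schema_version": SCHEMA_VERSION}
        out.update(copy.deepcopy(self._data))
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, SelectionSpec) and self._data == other._data

    # -- completeness ---------------------------------------------------
    def completeness(self) -> dict[str, bool]:
        """Per-section completeness flags (partial specs are legal)."""
        return {s: self._data[s] is not None for s in SECTIONS}

    def is_complete(self) -> bool:
        flags = self.completeness()
        if self.design == "cohort":
            return flags["endpoint"] and flags["start"] and flags["censoring"]
        return flags["metadata"]

    def require_complete(self) -> None:
        flags = self.completeness()
        if self.design == "cohort":
            missing = [s for s in ("endpoint", "start", "censoring") if not flags[s]]
            if missing:
                raise SpecificationError(
                    f"spec incomplete for cohort design; missing sections: {missing}")
        elif not flags["metadata"]:
            raise SpecificationError("cross_sectional spec needs a metadata section")

    # -- revision -------------------------------------------------------
    def revise(self, section: str, patch) -> "SelectionSpec":
        """Replace exactly one section; all others are untouched.  An
        empty patch returns the spec itself (no new version)."""
        if section not in SECTIONS:
            raise SpecificationError(f"unknown section {section!r}")
        if not patch:
            return self
        data = self.to_dict()
        data[section] = copy.deepcopy(patch)
        return SelectionSpec(data)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> Path:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
        elif path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=True),
                            encoding="utf-8")
        else:
            raise SpecificationError(f"unknown spec file extension: {path.suffix}")
        return path

    @classmethod
    def load(cls, path) -> "SelectionSpec":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix == ".json":
            try:
                data = json.loads(text)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path.name}: line {exc.lineno}: {exc.msg}") from exc
        elif path.suffix in (".yaml", ".yml"):
            try:
                data = yaml.safe_load(text)
            except yaml.YAMLError as exc:
                mark = getattr(exc, "problem_mark", None)
                line = mark.line + 1 if mark else "?"
                raise FormatError(f"{path.name}: line {line}: {exc}") from exc
        else:
            raise SpecificationError(f"unknown spec file extension: {path.suffix}")
        if not isinstance(data, dict):
            raise FormatError(f"{path.name}: spec file must contain a mapping")
        return cls(data)
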