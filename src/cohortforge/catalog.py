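"""Covariate catalog: search, hierarchical selection, the always-included
essential set, and derived covariates (BMI).

The catalog is the study's codebook: one entry per covariate column with a
label, type, optional value labels, and the questionnaire / section /
question tags that support hierarchical selection.  Every analytic dataset
automatically includes the 62-member essential set; this count is a
configuration contract enforced wherever the essential set is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, UnknownCovariateError

ESSENTIAL_COUNT = 62

CATALOG_COLUMNS = [
    "name", "label", "dtype", "value_labels", "questionnaire_number",
    "section", "question_number", "essential", "derived",
]

DTYPES = ("categorical", "continuous", "date", "flag")

#: survey column names feeding the derived BMI covariate
HEIGHT_COLUMN = "q1_height_m"
WEIGHT_COLUMN = "q1_weight_kg"


def parse_value_labels(text: str) -> dict[str, str]:
    """Parse ``"1=Never|2=Former|3=Current"`` into an ordered mapping."""
    if not text:
        return {}
    out: dict[str, str] = {}
    for pair in text.split("|"):
        code, _, label = pair.partition("=")
        out[code] = label
    return out


def format_value_labels(labels: dict[str, str]) -> str:
    return "|".join(f"{c}={l}" for c, l in labels.items())


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    label: str
    dtype: str
    value_labels: dict[str, str] = field(default_factory=dict)
    questionnaire_number: int | None = None
    section: str = ""
    question_number: str = ""
    essential: bool = False
    derived: bool = False

    @property
    def is_survey_item(self) -> bool:
        """True for columns that live in the surveys table (and hence obey
        missing-by-design masking); participant-domain and derived entries
        do not."""
        return not self.derived and self.section != "participant"


class Catalog:
    """Ordered collection of :class:`CatalogEntry`; order is stable and is
    the column order of every output that lists covariates."""

    def __init__(self, entries: list[CatalogEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate catalog names: {dupes}")
        for e in entries:
            if e.dtype not in DTYPES:
                raise ConfigurationError(f"{e.name}: unknown dtype {e.dtype!r}")
            if (e.dtype == "categorical") != bool(e.value_labels):
                raise ConfigurationError(
                    f"{e.name}: value_labels must be present iff dtype is categorical"
                )
            if not e.derived and not (e.questionnaire_number and e.section and e.question_number):
                raise ConfigurationError(
                    f"{e.name}: non-derived entries need questionnaire/section/question tags"
                )
        self.entries = list(entries)
        self._by_name = {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> CatalogEntry:
        return self._by_name[name]

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def survey_items(self) -> list[CatalogEntry]:
        return [e for e in self.entries if e.is_survey_item]

    # -- serialization -------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Catalog":
        missing = [c for c in CATALOG_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"catalog is missing columns: {missing}")
        entries = []
        for row in frame.itertuples(index=False):
            qn = str(row.questionnaire_number)
            entries.append(CatalogEntry(
                name=row.name,
                label=row.label,
                dtype=row.dtype,
                value_labels=parse_value_labels(row.value_labels),
                questionnaire_number=int(qn) if qn else None,
                section=row.section,
                question_number=row.question_number,
                essential=str(row.essential) in ("1", "True", "true"),
                derived=str(row.derived) in ("1", "True", "true"),
            ))
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "name": e.name,
            "label": e.label,
            "dtype": e.dtype,
            "value_labels": format_value_labels(e.value_labels),
            "questionnaire_number": "" if e.questionnaire_number is None else str(e.questionnaire_number),
            "section": e.section,
            "question_number": e.question_number,
            "essential": "1" if e.essential else "0",
            "derived": "1" if e.derived else "0",
        } for e in self.entries]
        return pd.DataFrame(rows, columns=CATALOG_COLUMNS, dtype=str)

    @classmethod
    def read_csv(cls, path) -> "Catalog":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_frame(frame)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


# -- selectors ---------------------------------------------------------

SELECTOR_KINDS = ("names", "questionnaire", "section", "question", "search")


@dataclass(frozen=True)
class CovariateSelector:
    """One hierarchical selection handle: explicit names, a questionnaire
    number, a section tag, a question number, or a free-text search term."""
    kind: str
    value: object

    def __post_init__(self):
        if self.kind not in SELECTOR_KINDS:
            raise ConfigurationError(f"unknown selector kind {self.kind!r}")
        if self.value in (None, "", [], ()):
            raise ConfigurationError("empty selector is not allowed")

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSelector":
        if len(d) != 1:
            raise ConfigurationError(f"selector must have exactly one key, got {sorted(d)}")
        kind, value = next(iter(d.items()))
        return cls(kind, tuple(value) if isinstance(value, list) else value)

    def to_dict(self) -> dict:
        value = list(self.value) if isinstance(self.value, tuple) else self.value
        return {self.kind: value}


def search_catalog(catalog: Catalog, term: str) -> list[CatalogEntry]:
    """Case-insensitive substring match over name and label, catalog order."""
    needle = term.lower()
    return [e for e in catalog.entries
            if needle in e.name.lower() or needle in e.label.lower()]


def _selector_matches(catalog: Catalog, selector: CovariateSelector) -> list[str]:
    if selector.kind == "names":
        names = [selector.value] if isinstance(selector.value, str) else list(selector.value)
        for n in names:
            if n not in catalog:
                raise UnknownCovariateError(f"unknown covariate {n!r}")
        keep = set(names)
        return [e.name for e in catalog.entries if e.name in keep]
    if selector.kind == "questionnaire":
        return [e.name for e in catalog.entries
                if e.questionnaire_number == int(selector.value)]
    if selector.kind == "section":
        return [e.name for e in catalog.entries if e.section == selector.value]
    if selector.kind == "question":
        return [e.name for e in catalog.entries if e.question_number == selector.value]
    return [e.name for e in search_catalog(catalog, selector.value)]


def select_covariates(catalog: Catalog, selectors: list[CovariateSelector],
                      include_essential: bool = True) -> list[str]:
    """Resolve selectors to a deduplicated, catalog-ordered name list.

    A pure function of (catalog, selectors): revising a selection is just
    re-running it.  The essential set is appended (in catalog order) when
    ``include_essential`` is true, so every dataset is a superset of it.
    """
    chosen: set[str] = set()
    for sel in selectors:
        chosen.update(_selector_matches(catalog, sel))
    if include_essential:
        chosen.update(e.name for e in essential_set(catalog))
    return [e.name for e in catalog.entries if e.name in chosen]


def essential_set(catalog: Catalog) -> list[CatalogEntry]:
    """The always-included covariates; the catalog must flag exactly 62."""
    flagged = [e for e in catalog.entries if e.essential]
    if len(flagged) != ESSENTIAL_COUNT:
        raise ConfigurationError(
            f"catalog flags {len(flagged)} essential covariates; exactly "
            f"{ESSENTIAL_COUNT} are required"
        )
    return flagged


# -- derived covariates ------------------------------------------------

def derive_bmi(height_m, weight_kg):
    """Body mass index, kg/m², from self-reported height and weight.

    Missing input propagates to missing output; a non-positive height with
    a present weight also yields missing (a data-quality flag is the
    caller's to log).  Accepts scalars or aligned pandas Series.
    """
    if isinstance(height_m, pd.Series) or isinstance(weight_kg, pd.Series):
        h = pd.to_numeric(height_m, errors="coerce")
        w = pd.to_numeric(weight_kg, errors="coerce")
        out = w / (h * h)
        return out.where(h > 0)
    if height_m is None or weight_kg is None:
        return None
    if not np.isfinite(height_m) or not np.isfinite(weight_kg) or height_m <= 0:
        return None
    return weight_kg / (height_m * height_m)
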