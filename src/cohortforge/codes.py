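"""Clinical code handling: ICD normalization, prefix matching, the
bundled SEER site-group recode subset, and organ-surgery procedure
code sets.

Matching semantics are normalized prefix matching throughout: codes are
uppercased, stripped and de-dotted before comparison ("C50.9" matches
prefix "C50").  The bundled SEER recode is a deliberately small, editable
subset of the public site-group recode covering the common sites of a
women's cancer cohort; a full table can be supplied as a CSV with the
same columns.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

from .errors import CodeFormatError, ConfigurationError, SpecificationError

SURGERY_GROUPS = ("breast", "uterus", "ovary")


def normalize_icd(code: str) -> str:
    """Canonicalize a raw ICD / ICD-O-3 code for matching.

    Uppercase, strip surrounding whitespace, drop embedded dots:
    ``"c50.9" -> "C509"``.  The original string is left to the caller for
    display purposes.
    """
    if code is None:
        raise CodeFormatError("empty code")
    canon = code.strip().upper().replace(".", "")
    if not canon or not canon.isalnum():
        raise CodeFormatError(f"malformed code: {code!r}")
    return canon


def icd_prefix_match(code: str, prefixes) -> bool:
    """True iff some prefix is a leading substring of the normalized code."""
    return any(code.startswith(p) for p in prefixes)


def normalize_prefixes(prefixes) -> frozenset[str]:
    return frozenset(normalize_icd(p) for p in prefixes)


class SeerRecodeMapping:
    """Ordered recode rules: histology ranges override site ranges."""

    def __init__(self, rules: list[tuple[str, str, str, str]]):
        for kind, lo, hi, label in rules:
            if kind not in ("histology", "site") or not label or lo > hi:
                raise ConfigurationError(f"malformed recode rule: {(kind, lo, hi, label)}")
        # histology-based overrides are applied before site ranges
        self.rules = sorted(rules, key=lambda r: 0 if r[0] == "histology" else 1)
        self.labels = sorted({r[3] for r in rules})

    @classmethod
    def from_csv(cls, path_or_handle) -> "SeerRecodeMapping":
        rows = _read_code_csv(path_or_handle, ("kind", "lo", "hi", "label"))
        return cls([(r["kind"], r["lo"], r["hi"], r["label"]) for r in rows])

    def recode(self, site_code: str, histology_code: str) -> str:
        site = normalize_icd(site_code)
        hist = normalize_icd(histology_code)
        for kind, lo, hi, label in self.rules:
            value = hist if kind == "histology" else site
            if lo <= value <= hi:
                return label
        return "other"


def _read_code_csv(path_or_handle, required_columns) -> list[dict]:
    if hasattr(path_or_handle, "read"):
        reader = csv.DictReader(path_or_handle)
        rows = list(reader)
        fieldnames = reader.fieldnames
    else:
        with open(path_or_handle, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            rows = list(reader)
            fieldnames = reader.fieldnames
    if fieldnames is None or list(fieldnames) != list(required_columns):
        raise ConfigurationError(
            f"code table must have columns {','.join(required_columns)}, got {fieldnames}"
        )
    return rows


@lru_cache(maxsize=1)
def default_seer_mapping() -> SeerRecodeMapping:
    with resources.files("cohortforge.data").joinpath("seer_recode.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return SeerRecodeMapping.from_csv(fh)


def seer_recode(site_code: str, histology_code: str, mapping: SeerRecodeMapping | None = None) -> str:
    """Map an ICD-O-3 (site, histology) pair to a site-group label or "other"."""
    mapping = mapping or default_seer_mapping()
    return mapping.recode(site_code, histology_code)


@lru_cache(maxsize=1)
def default_surgery_codes() -> dict[str, frozenset[str]]:
    """Bundled organ-surgery procedure-code prefixes by endpoint group.

    These are pluggable defaults: real-world code-set curation is a
    user-supplied configuration (CSV with columns
    endpoint_group,code_prefix,label).
    """
    with resources.files("cohortforge.data").joinpath("surgery_codes.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        rows = _read_code_csv(fh, ("endpoint_group", "code_prefix", "label"))
    sets: dict[str, set[str]] = {g: set() for g in SURGERY_GROUPS}
    for row in rows:
        group = row["endpoint_group"]
        if group not in sets:
            raise ConfigurationError(f"unknown endpoint group in surgery code table: {group}")
        sets[group].add(normalize_icd(row["code_prefix"]))
    return {g: frozenset(s) for g, s in sets.items()}


def load_surgery_codes(path) -> dict[str, frozenset[str]]:
    rows = _read_code_csv(path, ("endpoint_group", "code_prefix", "label"))
    sets: dict[str, set[str]] = {}
    for row in rows:
        if row["endpoint_group"] not in SURGERY_GROUPS:
            raise ConfigurationError(f"unknown endpoint group: {row['endpoint_group']}")
        sets.setdefault(row["endpoint_group"], set()).add(normalize_icd(row["code_prefix"]))
    return {g: frozenset(sets.get(g, set())) for g in SURGERY_GROUPS}


def check_surgery_group(group: str) -> str:
    if group not in SURGERY_GROUPS + ("none",):
        raise SpecificationError(f"unknown endpoint group {group!r}; expected one of "
                                 f"{', '.join(SURGERY_GROUPS + ('none',))}")
    return group
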