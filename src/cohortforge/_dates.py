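"""Calendar-date helpers.

Dates are ISO-8601 strings (``YYYY-MM-DD``) everywhere inside tables and
files.  The ``MM/DD/YYYY`` form is accepted only at the user-input
boundary (spec files, CLI prompts) and normalized on entry.
"""

from __future__ import annotations

import re
from datetime import date, timedelta

from .errors import FormatError

_ISO_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_US_RE = re.compile(r"^\d{1,2}/\d{1,2}/\d{4}$")


def parse_iso(value: str | None) -> date | None:
    """Parse an ISO date string; empty/None means missing."""
    if value is None or value == "":
        return None
    if not _ISO_RE.match(value):
        raise FormatError(f"not an ISO-8601 date: {value!r}")
    return date.fromisoformat(value)


def parse_user_date(value: str) -> date:
    """Parse a user-entered date: ISO, or MM/DD/YYYY (normalized on entry)."""
    value = value.strip()
    if _ISO_RE.match(value):
        return date.fromisoformat(value)
    if _US_RE.match(value):
        month, day, year = (int(p) for p in value.split("/"))
        return date(year, month, day)
    raise FormatError(f"unrecognized date {value!r}; use MM/DD/YYYY or YYYY-MM-DD")


def iso(d: date | None) -> str:
    return "" if d is None else d.isoformat()


def days_between(start: date, end: date) -> int:
    return (end - start).days


def add_days(d: date, n: int) -> date:
    return d + timedelta(days=n)
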