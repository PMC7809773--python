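"""Validation and normalization of identifying data (IDAT) before matching.

Raw person records (first name, last name, day/month/year of birth) are
validated against calendar rules, transcribed to uppercase ASCII with
German umlaut expansion, and split into compound-name components.  All
downstream matching and encoding operates on :class:`NormalizedRecord`.
"""

from __future__ import annotations

import calendar
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "RawRecord",
    "NormalizedRecord",
    "ValidationFinding",
    "normalize_field",
    "split_compound",
    "validate_record",
    "normalize_record",
    "read_records_csv",
    "MIN_YEAR",
    "MAX_YEAR",
]

# Plausible birth-year window for a patient registry (proleptic Gregorian).
MIN_YEAR = 1850
MAX_YEAR = 2100

# German civil-register transcription: umlauts expand, they are not stripped.
_UMLAUT_MAP = {
    "Ä": "AE",
    "Ö": "OE",
    "Ü": "UE",
    "ä": "AE",
    "ö": "OE",
    "ü": "UE",
    "ß": "SS",
    "ẞ": "SS",
}


@dataclass(frozen=True)
class RawRecord:
    """A person record as received from a data holder, fields unvalidated.

    Empty strings and ``None`` both denote a missing value.
    """

    first_name: Optional[Union[str, int]] = None
    last_name: Optional[Union[str, int]] = None
    birth_day: Optional[Union[str, int]] = None
    birth_month: Optional[Union[str, int]] = None
    birth_year: Optional[Union[str, int]] = None
    record_id: Optional[str] = None


@dataclass(frozen=True)
class ValidationFinding:
    """One validation result: which field violated which rule.

    ``severity`` is ``"error"`` for invalid content and ``"missing"`` for an
    absent field; missing fields are reported, not rejected.
    """

    field: str
    rule: str
    message: str
    severity: str = "error"


@dataclass(frozen=True)
class NormalizedRecord:
    """Cleaned IDAT: uppercase ASCII names with compound components,
    birth fields as validated integers (``None`` = missing)."""

    first_name: Optional[str] = None
    first_components: tuple = ()
    last_name: Optional[str] = None
    last_components: tuple = ()
    birth_day: Optional[int] = None
    birth_month: Optional[int] = None
    birth_year: Optional[int] = None
    record_id: Optional[str] = None

    def name_components(self, fld: str) -> tuple:
        if fld == "first_name":
            return self.first_components
        if fld == "last_name":
            return self.last_components
        raise KeyError(fld)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and pd.isna(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def normalize_field(value: Optional[str]) -> str:
    """Normalize a name string: trim, collapse whitespace, uppercase,
    transcribe German umlauts (ä→AE, ß→SS) and strip other diacritics
    to their base letter.  Idempotent; empty input yields ``""``.
    """
    if value is None:
        return ""
    # NFC first so combining-diaeresis umlauts hit the transcription table
    text = unicodedata.normalize("NFC", str(value))
    text = "".join(_UMLAUT_MAP.get(ch, ch) for ch in text)
    # NFKD before upper: compatibility characters (ligatures, math
    # alphabets) decompose to ASCII that still needs case folding
    text = unicodedata.normalize("NFKD", text).upper()
    text = "".join(c for c in text if not unicodedata.combining(c))
    # keep only ASCII; anything else (rare) is dropped
    text = text.encode("ascii", "ignore").decode("ascii")
    return " ".join(text.split())


def split_compound(value: str) -> list:
    """Split a normalized name on whitespace and hyphens into components.

    Empty components are dropped; order is preserved.
    """
    if not value:
        return []
    return [c for c in value.replace("-", " ").split() if c]


def _check_int(value, lo: int, hi: int):
    """Parse an integer field; returns (int-or-None, rule-violation-or-None)."""
    try:
        iv = int(str(value).strip())
    except (TypeError, ValueError):
        return None, "not-an-integer"
    if not lo <= iv <= hi:
        return iv, "out-of-range"
    return iv, None


def validate_record(r: RawRecord) -> list:
    """Validate a raw record; returns findings (never raises).

    An empty list means every present field is valid.  Missing fields
    produce findings with severity ``"missing"``.  Date validity follows
    the proleptic Gregorian calendar (e.g. month 13 or 31 April are
    invalid, 29-02-2000 is valid).
    """
    findings = []
    for fld in ("first_name", "last_name"):
        if _is_missing(getattr(r, fld)):
            findings.append(
                ValidationFinding(fld, "missing", f"{fld} is missing", "missing")
            )

    parsed = {}
    for fld, lo, hi in (
        ("birth_day", 1, 31),
        ("birth_month", 1, 12),
        ("birth_year", MIN_YEAR, MAX_YEAR),
    ):
        value = getattr(r, fld)
        if _is_missing(value):
            findings.append(
                ValidationFinding(fld, "missing", f"{fld} is missing", "missing")
            )
            parsed[fld] = None
            continue
        iv, rule = _check_int(value, lo, hi)
        if rule is not None:
            findings.append(
                ValidationFinding(fld, rule, f"{fld}={value!r} violates {rule} [{lo},{hi}]")
            )
            parsed[fld] = None
        else:
            parsed[fld] = iv

    day, month, year = parsed["birth_day"], parsed["birth_month"], parsed["birth_year"]
    if day is not None and month is not None:
        # day-in-month check needs the year for February; missing year: allow 29
        if year is not None:
            max_day = calendar.monthrange(year, month)[1]
        else:
            max_day = [31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1]
        if day > max_day:
            findings.append(
                ValidationFinding(
                    "birth_day",
                    "invalid-day-for-month",
                    f"day {day} does not exist in month {month}" + (f" of {year}" if year else ""),
                )
            )
    return findings


def normalize_record(r: RawRecord) -> NormalizedRecord:
    """Transform a raw record into its normalized form.

    Invalid date components become missing; callers that must reject
    invalid input should run :func:`validate_record` first.
    """
    first = normalize_field(r.first_name if not _is_missing(r.first_name) else None)
    last = normalize_field(r.last_name if not _is_missing(r.last_name) else None)

    def _num(value, lo, hi):
        if _is_missing(value):
            return None
        iv, rule = _check_int(value, lo, hi)
        return iv if rule is None else None

    return NormalizedRecord(
        first_name=first or None,
        first_components=tuple(split_compound(first)),
        last_name=last or None,
        last_components=tuple(split_compound(last)),
        birth_day=_num(r.birth_day, 1, 31),
        birth_month=_num(r.birth_month, 1, 12),
        birth_year=_num(r.birth_year, MIN_YEAR, MAX_YEAR),
        record_id=r.record_id,
    )


def read_records_csv(path: Union[str, Path], delimiter: str = ",") -> list:
    """Read raw records from a CSV file.

    Expects a header with first_name,last_name,birth_day,birth_month,
    birth_year and optionally record_id; empty cells are missing values.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list:
    """Convert a DataFrame (string or numeric columns) to RawRecords."""
    recs = []
    has_id = "record_id" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        recs.append(
            RawRecord(
                first_name=d.get("first_name"),
                last_name=d.get("last_name"),
                birth_day=d.get("birth_day"),
                birth_month=d.get("birth_month"),
                birth_year=d.get("birth_year"),
                record_id=str(d["record_id"]) if has_id else f"row{i}",
            )
        )
    return recs
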