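"""Event-log record model and the TSV log dialect.

A log file is UTF-8 TSV with header ``patient_id\ttimestamp\tevent\tfunction``.
``event`` is one of ``login``, ``logout``, ``click``; ``function`` is one of the
30 portal function codes for clicks and empty otherwise.  Timestamps are
ISO-8601 at second (or finer) resolution; one file carries one implicit
timezone (UTC by convention) and all arithmetic downstream uses differences
only, so records are held as naive datetimes.

The function vocabulary is closed: unknown tokens raise ``VocabularyError``
unless an explicit alias table maps them, so silent click loss is impossible.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import IO, Iterable, Mapping

__all__ = [
    "FUNCTION_CODES",
    "EVENT_KINDS",
    "LogRecord",
    "LogParseError",
    "VocabularyError",
    "canonicalize_function",
    "read_log",
    "write_log",
]

#: The closed vocabulary of portal function codes.
FUNCTION_CODES: tuple[str, ...] = (
    "labresults",
    "labtests",
    "resultcomponentgraphing",
    "encounterreview",
    "encounterdetails",
    "allergies",
    "immunizations",
    "problemlist",
    "messaging",
    "flowsheetreportslist",
    "flowsheetreportdetails",
    "healthmaintenance",
    "healthmaintenanceschedule",
    "healthsnapshot",
    "histories",
    "letters",
    "medication",
    "medicationrenewalrequest",
    "patientnotes",
    "personlpreferences",
    "demographics",
    "providerdetails",
    "addresschangerequest",
    "referralreview",
    "referralrequest",
    "appt_final",
    "proxyaccessview",
    "customerservicerequest",
    "drivingdirections",
    "switchcontext",
)

_FUNCTION_SET = frozenset(FUNCTION_CODES)

EVENT_KINDS = ("login", "logout", "click")

HEADER = ("patient_id", "timestamp", "event", "function")

#: Timestamp format written by :func:`write_log`.
_TS_FMT = "%Y-%m-%dT%H:%M:%S"


class LogParseError(ValueError):
    """A structurally malformed log row (bad timestamp, missing field...)."""


class VocabularyError(ValueError):
    """A function token outside the closed vocabulary and the alias table."""


def canonicalize_function(token: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a free-form token to a vocabulary function code.

    Matching is case-insensitive on the canonical names; ``aliases`` maps
    additional spellings (keys matched case-insensitively too) onto canonical
    codes.  Raises :class:`VocabularyError` for anything else.
    """
    folded = token.strip().lower()
    if folded in _FUNCTION_SET:
        return folded
    if aliases:
        for alias, target in aliases.items():
            if alias.strip().lower() == folded:
                if target not in _FUNCTION_SET:
                    raise VocabularyError(
                        f"alias {alias!r} maps to {target!r}, which is not a vocabulary code"
                    )
                return target
    raise VocabularyError(f"unknown function token {token!r}")


@dataclass(frozen=True, slots=True)
class LogRecord:
    """One time-stamped portal event for one patient."""

    patient_id: str
    timestamp: datetime
    event: str  # login | logout | click
    function: str | None = None  # vocabulary code, present iff event == "click"

    def __post_init__(self) -> None:
        if self.event not in EVENT_KINDS:
            raise LogParseError(f"unknown event kind {self.event!r}")
        if self.event == "click":
            if self.function is None:
                raise LogParseError("click record requires a function code")
            if self.function not in _FUNCTION_SET:
                raise VocabularyError(f"unknown function token {self.function!r}")
        elif self.function is not None:
            raise LogParseError(f"{self.event} record must not carry a function")


def _open_maybe(source, mode: str) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def _parse_timestamp(text: str, lineno: int) -> datetime:
    try:
        ts = datetime.fromisoformat(text.strip())
    except ValueError as exc:
        raise LogParseError(f"line {lineno}: malformed timestamp {text!r}") from exc
    if ts.tzinfo is not None:
        # one declared timezone per file: normalise to naive
        ts = ts.replace(tzinfo=None)
    return ts


def read_log(
    source: str | Path | IO[str],
    aliases: Mapping[str, str] | None = None,
) -> list[LogRecord]:
    """Read a TSV event log into records sorted by (patient_id, timestamp).

    Sorting is stable: records with equal (patient, timestamp) keep file order.
    Malformed rows raise :class:`LogParseError` naming the 1-based line number;
    unknown function tokens raise :class:`VocabularyError` naming the token.
    """
    fh, close = _open_maybe(source, "r")
    try:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LogParseError("empty file: missing header row")
        if tuple(h.strip() for h in header) != HEADER:
            raise LogParseError(
                f"bad header {header!r}; expected {list(HEADER)!r}"
            )
        records: list[LogRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise LogParseError(f"line {lineno}: expected 4 fields, got {len(row)}")
            pid, ts_text, event, fn_text = (field.strip() for field in row)
            if not pid:
                raise LogParseError(f"line {lineno}: missing patient_id")
            if event not in EVENT_KINDS:
                raise LogParseError(f"line {lineno}: unknown event kind {event!r}")
            ts = _parse_timestamp(ts_text, lineno)
            function: str | None = None
            if event == "click":
                if not fn_text:
                    raise LogParseError(f"line {lineno}: click without function code")
                function = canonicalize_function(fn_text, aliases)
            elif fn_text:
                raise LogParseError(
                    f"line {lineno}: {event} record carries function {fn_text!r}"
                )
            records.append(LogRecord(pid, ts, event, function))
    finally:
        if close:
            fh.close()
    # stable sort => equal-timestamp records keep input order
    records.sort(key=lambda r: (r.patient_id, r.timestamp))
    return records


def write_log(records: Iterable[LogRecord], sink: str | Path | IO[str]) -> None:
    """Write records in the TSV dialect; ``read_log(write_log(x)) == sorted(x)``."""
    fh, close = _open_maybe(sink, "w")
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HEADER)
        for rec in records:
            writer.writerow(
                (
                    rec.patient_id,
                    rec.timestamp.strftime(_TS_FMT),
                    rec.event,
                    rec.function or "",
                )
            )
    finally:
        if close:
            fh.close()


def records_to_string(records: Iterable[LogRecord]) -> str:
    """Render records as the TSV dialect in memory (convenience for tests/CLI)."""
    buf = io.StringIO()
    write_log(records, buf)
    return buf.getvalue()
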