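"""Audits of non-taxonomic processing defects in paired occurrence records.

Aggregator processing can silently blank supplied field values, reject or
truncate dates, mangle collector-name strings while atomising them, map
geodetic datums to the wrong EPSG code, and assign the wrong country from
bad coordinates.  Each audit here takes original/processed value pairs and
emits a structured finding; aggregation over a dataset is left to callers
(see :mod:`dwcaudit.cli`).

The date grammar is normative for this package: a "valid" entry is anything
that classifies to a class other than ``MALFORMED``.  Interval shorthand
follows ISO 8601 abbreviation: ``1943-06-20/21`` borrows year and month from
the start, ``1999-03-04/05-06`` borrows the year.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass, field
from datetime import date

__all__ = [
    "FieldLossReport",
    "DateAudit",
    "AgentAudit",
    "GeoAudit",
    "ElevationResult",
    "field_loss",
    "classify_date",
    "audit_date_processing",
    "audit_agent",
    "audit_datum",
    "convert_verbatim_elevation",
    "depth_summary",
    "audit_country",
    "DEFAULT_DATUM_MAP",
    "DEFAULT_COUNTRY_CODES",
    "DATE_FORMAT_CLASSES",
    "summarize_dates",
    "summarize_agents",
    "summarize_datums",
    "summarize_countries",
]

FEET_TO_METRES = 0.3048

DATE_FORMAT_CLASSES = (
    "Y",
    "YM",
    "YMD",
    "YMD_loose",
    "INTERVAL_DD",
    "INTERVAL_MD",
    "INTERVAL_YMD",
    "INTERVAL_Y",
    "INTERVAL_YM",
    "DATETIME_TZ",
    "DATETIME_FRAC_TZ",
    "MALFORMED",
)

#: Datum label -> EPSG code.  Extensible via config; labels are compared
#: case-insensitively with internal spaces removed ("WGS 84" == "WGS84").
DEFAULT_DATUM_MAP = {
    "WGS84": "EPSG:4326",
    "AGD66": "EPSG:6202",
    "AGD84": "EPSG:6203",
    "GDA94": "EPSG:4283",
}

#: Minimal country-name <-> ISO 3166-1 alpha-2 table for country audits.
DEFAULT_COUNTRY_CODES = {
    "Australia": "AU",
    "New Zealand": "NZ",
    "Mozambique": "MZ",
    "Namibia": "NA",
    "Botswana": "BW",
    "South Africa": "ZA",
    "Indonesia": "ID",
    "Papua New Guinea": "PG",
}


def _blank(s: str | None) -> bool:
    return s is None or not s.strip()


# ---------------------------------------------------------------------------
# Field-level data loss


@dataclass
class FieldLossReport:
    """Per-term loss tally: a loss is a non-blank original value whose
    processed counterpart is blank (or whose column is absent)."""

    term: str
    supplied: int = 0
    lost: int = 0
    never_supplied: int = 0
    retained: int = 0
    loss_fraction: float = 0.0
    term_missing_in_processed: bool = False


def field_loss(pairs, term: str) -> FieldLossReport:
    """Count data loss for one Darwin Core term over paired records.

    Blank means empty or whitespace-only.  When the processed side never
    carries the column at all the report is flagged
    (``term_missing_in_processed``) — values present only on the original
    side then all count as lost if supplied.
    """
    report = FieldLossReport(term=term)
    seen_processed_column = False
    for pair in pairs:
        orig = pair.original.get(term)
        proc = pair.processed.get(term)
        if term in pair.processed:
            seen_processed_column = True
        if _blank(orig):
            report.never_supplied += 1
            continue
        report.supplied += 1
        if _blank(proc):
            report.lost += 1
        else:
            report.retained += 1
    report.loss_fraction = report.lost / report.supplied if report.supplied else 0.0
    report.term_missing_in_processed = not seen_processed_column
    return report


# ---------------------------------------------------------------------------
# Dates

_RE_Y = re.compile(r"^(\d{4})$")
_RE_YM = re.compile(r"^(\d{4})-(\d{1,2})$")
_RE_YMD = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_RE_DT = re.compile(
    r"^(\d{4})-(\d{2})-(\d{2})T\d{2}:\d{2}:\d{2}(?P<frac>\.\d+)?(Z|[+-]\d{2}:?\d{2})$"
)
_RE_END_D = re.compile(r"^(\d{1,2})$")
_RE_END_MD = re.compile(r"^(\d{1,2})-(\d{1,2})$")
_RE_END_Y = re.compile(r"^(\d{4})$")
_RE_END_YM = re.compile(r"^(\d{4})-(\d{1,2})$")
_RE_END_YMD = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")


@dataclass
class DateAudit:
    """Format classification and processing outcome for one date value."""

    raw: str
    format_class: str = "MALFORMED"
    interval_start: date | None = None
    interval_end: date | None = None
    outcome: str = "not_applicable"


def _mkdate(y: int, m: int, d: int) -> date | None:
    try:
        return date(y, m, d)
    except ValueError:
        return None


def _month_end(y: int, m: int) -> date | None:
    if not 1 <= m <= 12:
        return None
    return date(y, m, calendar.monthrange(y, m)[1])


def classify_date(raw: str) -> DateAudit:
    """Classify a date string against the format grammar.

    Single dates, ISO interval shorthands and timezone datetimes are
    recognised; anything else — including an interval whose expanded start
    exceeds its end — is ``MALFORMED``.
    """
    audit = DateAudit(raw=raw or "")
    text = (raw or "").strip()
    if not text:
        return audit

    m = _RE_DT.match(text)
    if m:
        start = _mkdate(int(m.group(1)), int(m.group(2)), int(m.group(3)))
        if start is None:
            return audit
        audit.format_class = "DATETIME_FRAC_TZ" if m.group("frac") else "DATETIME_TZ"
        audit.interval_start = start
        return audit

    if "/" in text:
        start_s, _, end_s = text.partition("/")
        ms = _RE_YMD.match(start_s)
        if not ms:
            return audit
        start = _mkdate(int(ms.group(1)), int(ms.group(2)), int(ms.group(3)))
        if start is None:
            return audit
        end: date | None
        if _RE_END_YMD.match(end_s):
            me = _RE_END_YMD.match(end_s)
            end = _mkdate(int(me.group(1)), int(me.group(2)), int(me.group(3)))
            cls = "INTERVAL_YMD"
        elif _RE_END_YM.match(end_s):
            me = _RE_END_YM.match(end_s)
            end = _month_end(int(me.group(1)), int(me.group(2)))
            cls = "INTERVAL_YM"
        elif _RE_END_Y.match(end_s):
            end = date(int(end_s), 12, 31)
            cls = "INTERVAL_Y"
        elif _RE_END_MD.match(end_s):
            me = _RE_END_MD.match(end_s)
            end = _mkdate(start.year, int(me.group(1)), int(me.group(2)))
            cls = "INTERVAL_MD"
        elif _RE_END_D.match(end_s):
            end = _mkdate(start.year, start.month, int(end_s))
            cls = "INTERVAL_DD"
        else:
            return audit
        if end is None or start > end:
            return audit
        audit.format_class = cls
        audit.interval_start = start
        audit.interval_end = end
        return audit

    m = _RE_YMD.match(text)
    if m:
        ys, mos, ds = m.groups()
        d = _mkdate(int(ys), int(mos), int(ds))
        if d is None:
            return audit
        audit.interval_start = d
        audit.format_class = "YMD" if len(mos) == 2 and len(ds) == 2 else "YMD_loose"
        return audit
    m = _RE_YM.match(text)
    if m:
        if not 1 <= int(m.group(2)) <= 12:
            return audit
        audit.format_class = "YM"
        return audit
    if _RE_Y.match(text):
        audit.format_class = "Y"
        return audit
    return audit


def audit_date_processing(raw: str, processed: str) -> DateAudit:
    """Classify a raw date and judge what processing did with it.

    Outcomes: ``excluded`` (valid raw, blank processed),
    ``accepted_start_only`` (processed equals the interval's start date),
    ``accepted_full`` (processed preserves the raw content),
    ``altered`` (any other non-blank processed value),
    ``not_applicable`` (blank raw, or nothing valid to lose).
    """
    audit = classify_date(raw)
    if _blank(raw):
        return audit
    if _blank(processed):
        audit.outcome = "excluded" if audit.format_class != "MALFORMED" else "not_applicable"
        return audit
    proc = processed.strip()
    is_interval = audit.format_class.startswith("INTERVAL_")
    if is_interval and audit.interval_start is not None and proc == audit.interval_start.isoformat():
        audit.outcome = "accepted_start_only"
    elif proc == raw.strip():
        audit.outcome = "accepted_full"
    elif (
        not is_interval
        and audit.interval_start is not None
        and proc == audit.interval_start.isoformat()
    ):
        # e.g. "1999-1-2" normalised to "1999-01-02"
        audit.outcome = "accepted_full"
    else:
        audit.outcome = "altered"
    return audit


# ---------------------------------------------------------------------------
# Agent strings (recordedBy / identifiedBy)

AGENT_PATTERNS = (
    "null_replacement",
    "conjunction_failure",
    "initial_reversal",
    "added_initial",
    "initial_comma",
    "surname_ending_truncation",
    "unchanged",
    "changed_ok",
)

_RE_REVERSAL = re.compile(
    r"^(?P<sur>[A-Za-z'\-]+),\s*(?P<first>[A-Za-z'\-]{2,})\s+(?P<mid>[A-Za-z])\.?$"
)
_RE_ADDED = re.compile(r"^(?P<sur>[A-Za-z'\-]+),\s*(?P<first>[A-Za-z'\-]{2,})$")


@dataclass
class AgentAudit:
    """Corruption patterns observed in one agent-string processing step."""

    raw: str
    processed: str
    patterns: frozenset = field(default_factory=frozenset)


def _agent_surname(s: str) -> str:
    """Surname of one agent string: text before the first comma when the
    string is in 'Surname, Rest' form, else the final alphabetic token of
    length > 1 ('I.J.Surname' forms).  Heuristic and configurable in spirit;
    see docs/methods.md."""
    s = s.strip()
    if not s:
        return ""
    head, comma, _ = s.partition(",")
    if comma and head.strip():
        return head.strip()
    tokens = re.findall(r"[A-Za-z'\-]{2,}", s)
    return tokens[-1] if tokens else ""


def _raw_segments(raw: str) -> list[str]:
    parts = re.split(r"\s*(?:&|;|\||\band\b)\s*", raw)
    return [p for p in (p.strip() for p in parts) if p]


def audit_agent(raw: str, processed: str) -> AgentAudit:
    """Detect systematic corruption patterns in agent-name processing.

    The processed side uses pipe (``|``) as the multi-agent separator.
    Detectors are independent and a single pair can fire several; raw equal
    to processed yields exactly ``{"unchanged"}``.
    """
    if (raw or "") == (processed or ""):
        return AgentAudit(raw=raw, processed=processed, patterns=frozenset({"unchanged"}))

    patterns: set[str] = set()
    elements = [e.strip() for e in (processed or "").split("|")]
    live = [e for e in elements if e and e.lower() != "null"]

    if any(e.lower() == "null" for e in elements if e):
        patterns.add("null_replacement")

    if (processed or "").startswith(","):
        patterns.add("initial_comma")

    raw_tokens = {t.lower() for t in re.findall(r"[A-Za-z'\-]+", raw or "")}
    segments = _raw_segments(raw or "")
    seg_surnames = [_agent_surname(s) for s in segments]

    # surname ending in "and" read as a conjunction and cut off
    truncated_forms: set[str] = set()
    for sur in seg_surnames:
        if len(sur) > 4 and sur.lower().endswith("and"):
            stem = sur[:-3]
            if stem.lower() not in raw_tokens and any(
                stem.lower() == _agent_surname(e).lower() or stem.lower() in e.lower().split()
                for e in live
            ):
                if not any(sur.lower() in e.lower() for e in live):
                    patterns.add("surname_ending_truncation")
                    truncated_forms.add(stem.lower())

    # first name / middle initial transpositions
    for seg in segments:
        m = _RE_REVERSAL.match(seg)
        if m:
            expected = f"{m.group('sur')}, {m.group('mid')}. {m.group('first')}"
            if expected in live:
                patterns.add("initial_reversal")
            continue
        m = _RE_ADDED.match(seg)
        if m and "." not in seg:
            first = m.group("first")
            expected = f"{m.group('sur')}, {first[0]}. {first}"
            if expected in live:
                patterns.add("added_initial")

    # conjunction failure: surname fan-out or an underivable surname
    surname_counts: dict[str, int] = {}
    for e in live:
        sur = _agent_surname(e)
        if sur:
            surname_counts[sur.lower()] = surname_counts.get(sur.lower(), 0) + 1
    for sur, count in surname_counts.items():
        if count >= 2:
            initial_only = sum(
                1 for s in segments if not re.findall(r"[A-Za-z'\-]{2,}", s)
            )
            holders = sum(1 for s in seg_surnames if s.lower() == sur)
            if holders + initial_only < count:
                patterns.add("conjunction_failure")
    for e in live:
        sur = _agent_surname(e).lower()
        if sur and sur not in raw_tokens and sur not in truncated_forms:
            patterns.add("conjunction_failure")

    if not patterns:
        patterns.add("changed_ok")
    return AgentAudit(raw=raw, processed=processed, patterns=frozenset(patterns))


# ---------------------------------------------------------------------------
# Geodetic datum / country


@dataclass
class GeoAudit:
    """Verdicts on geodetic-datum mapping and country assignment."""

    raw_datum: str = ""
    processed_datum: str = ""
    datum_verdict: str = ""
    raw_country: str = ""
    processed_country_or_code: str = ""
    country_verdict: str = ""


def _norm_label(s: str) -> str:
    return re.sub(r"\s+", "", (s or "")).upper()


def audit_datum(raw: str, processed: str, mapping: dict[str, str] | None = None) -> GeoAudit:
    """Check one datum-label -> EPSG-code processing step against a mapping
    table (e.g. WGS84 -> EPSG:4326, AGD66 -> EPSG:6202)."""
    mapping = mapping if mapping is not None else DEFAULT_DATUM_MAP
    table = {_norm_label(k): v for k, v in mapping.items()}
    audit = GeoAudit(raw_datum=raw or "", processed_datum=processed or "")
    if _blank(processed):
        audit.datum_verdict = "deleted" if not _blank(raw) else "unmapped"
        return audit
    expected = table.get(_norm_label(raw))
    if expected is None:
        audit.datum_verdict = "unmapped"
    elif _norm_label(processed) == _norm_label(expected):
        audit.datum_verdict = "correct"
    else:
        audit.datum_verdict = "incorrect_mapping"
    return audit


_RE_ELEV = re.compile(
    r"^\s*(?P<a>\d+(?:\.\d+)?)"
    r"(?:\s*[–—-]\s*(?P<b>\d+(?:\.\d+)?))?"
    r"\s*(?P<unit>m|metres|meters|ft|feet|')?\.?\s*$",
    re.IGNORECASE,
)


@dataclass
class ElevationResult:
    """Outcome of converting a verbatim elevation/depth string to metres."""

    kind: str  # "value" | "interval" | "unparseable"
    value_m: float | None = None
    min_m: float | None = None
    max_m: float | None = None


def convert_verbatim_elevation(raw: str) -> ElevationResult:
    """Convert a verbatim elevation string to metres.

    Plain numbers are metres as given; ``ft``/``feet``/``'`` are multiplied
    by exactly 0.3048; ranges ("15000–17000 ft") convert both endpoints.
    Anything else is unparseable — a blank processed value against a
    parseable raw one is a flagged loss.
    """
    m = _RE_ELEV.match(raw or "")
    if not m:
        return ElevationResult(kind="unparseable")
    unit = (m.group("unit") or "m").lower()
    factor = FEET_TO_METRES if unit in ("ft", "feet", "'") else 1.0
    a = float(m.group("a")) * factor
    if m.group("b") is not None:
        b = float(m.group("b")) * factor
        return ElevationResult(kind="interval", min_m=a, max_m=b)
    return ElevationResult(kind="value", value_m=a)


def depth_summary(min_v: float, max_v: float) -> tuple[float, float]:
    """Collapse a min/max depth (or elevation) pair the way GBIF does:
    centre = mean of the endpoints, accuracy = average deviation from it.

    Raises ``ValueError`` when min exceeds max (invalid-range finding).
    """
    if min_v > max_v:
        raise ValueError(f"invalid range: min {min_v} > max {max_v}")
    return ((min_v + max_v) / 2.0, (max_v - min_v) / 2.0)


def audit_country(
    raw_country: str,
    processed_country_or_code: str,
    code_map: dict[str, str] | None = None,
) -> GeoAudit:
    """Compare the provider's country string with the aggregator's processed
    country or ISO code, via a name <-> code table."""
    code_map = code_map if code_map is not None else DEFAULT_COUNTRY_CODES
    audit = GeoAudit(
        raw_country=raw_country or "",
        processed_country_or_code=processed_country_or_code or "",
    )
    if _blank(raw_country) or _blank(processed_country_or_code):
        audit.country_verdict = "not_assessable"
        return audit
    by_name = {k.strip().lower(): v.upper() for k, v in code_map.items()}
    raw_l = raw_country.strip().lower()
    proc_l = processed_country_or_code.strip().lower()
    raw_code = by_name.get(raw_l, raw_l.upper() if len(raw_l) == 2 else None)
    proc_code = by_name.get(proc_l, proc_l.upper() if len(proc_l) == 2 else None)
    if raw_l == proc_l or (raw_code and proc_code and raw_code == proc_code):
        audit.country_verdict = "match"
    else:
        audit.country_verdict = "mismatch"
    return audit


# ---------------------------------------------------------------------------
# Dataset-level summaries (used by the CLI and by manifest-recovery tests)


def summarize_dates(pairs, term: str = "eventDate"):
    """Counter of (format_class, outcome) over records with a non-blank raw
    value for ``term``."""
    from collections import Counter

    counts: Counter = Counter()
    for pair in pairs:
        raw = pair.original.get(term, "")
        if _blank(raw):
            continue
        audit = audit_date_processing(raw, pair.processed.get(term, ""))
        counts[(audit.format_class, audit.outcome)] += 1
    return counts


def summarize_agents(pairs, term: str = "recordedBy"):
    """Counter of corruption patterns over records with a non-blank raw
    value for ``term``; every pattern a record fires is counted."""
    from collections import Counter

    counts: Counter = Counter()
    for pair in pairs:
        raw = pair.original.get(term, "")
        if _blank(raw):
            continue
        audit = audit_agent(raw, pair.processed.get(term, ""))
        for pattern in audit.patterns:
            counts[pattern] += 1
    return counts


def summarize_datums(pairs, mapping: dict[str, str] | None = None):
    """Counter of datum verdicts over records with a non-blank raw datum."""
    from collections import Counter

    counts: Counter = Counter()
    for pair in pairs:
        raw = pair.original.get("geodeticDatum", "")
        if _blank(raw):
            continue
        audit = audit_datum(raw, pair.processed.get("geodeticDatum", ""), mapping)
        counts[audit.datum_verdict] += 1
    return counts


def summarize_countries(pairs, code_map: dict[str, str] | None = None):
    """Counter of country verdicts; the processed side may carry ``country``
    or ``countryCode`` (GBIF drops ``country`` in processing)."""
    from collections import Counter

    counts: Counter = Counter()
    for pair in pairs:
        raw = pair.original.get("country", "")
        proc = pair.processed.get("country") or pair.processed.get("countryCode", "")
        audit = audit_country(raw, proc)
        if code_map is not None:
            audit = audit_country(raw, proc, code_map)
        counts[audit.country_verdict] += 1
    return counts
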