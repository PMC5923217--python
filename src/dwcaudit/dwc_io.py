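"""Reading and writing paired original/processed Darwin Core occurrence data.

Two dialects are supported:

* **ALA-style TSV** — a single tab-separated download where each audited term
  appears as a processed column plus a ``_raw``-suffixed original column.
  ALA downloads contain duplicated and mislabeled columns which this reader
  resolves positionally: simple duplicates (two ``basisOfRecord``, three
  ``recordedBy_raw``) collapse to the first non-blank value, and the second
  ``specificEpithet`` column — which actually holds the originally supplied
  species epithet — is remapped to the original side.

* **GBIF-style Darwin Core archive** — a directory (or zip) holding
  ``verbatim.txt`` (as supplied) and ``occurrence.txt`` (as processed),
  joined on the core record id.  ``meta.xml`` is honoured when present;
  otherwise the header rows name the columns.  Columns present in only one
  table stay on that side (GBIF drops e.g. ``scientificNameAuthorship``
  during processing).

Field maps never contain absent columns, so "present but blank" is
distinguishable from "column absent".  Files are decoded as UTF-8 with
replacement on error; TSV cells are taken verbatim (no quote interpretation).
"""

from __future__ import annotations

import csv
import io
import os
import zipfile
from collections import Counter
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from typing import NamedTuple
from xml.etree import ElementTree

from .change_classifier import NameChange

__all__ = [
    "RecordPair",
    "FieldMapping",
    "ReadResult",
    "AlignResult",
    "DialectError",
    "read_ala_table",
    "read_gbif_dwca",
    "align_pairs",
    "dedupe_by_modified",
    "write_change_table",
    "read_change_table",
]


class DialectError(ValueError):
    """The file does not look like the expected dialect (e.g. no header)."""


@dataclass
class RecordPair:
    """One occurrence record's original and processed field maps."""

    record_id: str
    catalog_number: str
    original: dict[str, str]
    processed: dict[str, str]
    source: str = "ALA"
    dataset_tag: str = ""


@dataclass
class FieldMapping:
    """How physical columns map to Darwin Core terms for one dialect.

    ``raw_column_for`` / ``processed_column_for`` hold explicit overrides;
    columns not listed are mapped by the dialect's naming convention
    (``_raw`` suffix for ALA).  ``known_quirks`` names the structural quirks
    the reader should resolve.
    """

    source_dialect: str = "ALA_TSV"
    raw_column_for: dict[str, str] = dc_field(default_factory=dict)
    processed_column_for: dict[str, str] = dc_field(default_factory=dict)
    known_quirks: list[str] = dc_field(
        default_factory=lambda: ["duplicate_columns", "second_specificEpithet_is_raw"]
    )
    id_columns: tuple[str, ...] = ("id", "recordID", "uuid", "occurrenceID")


class ReadResult(list):
    """A list of :class:`RecordPair` with per-row errors and warnings."""

    def __init__(self, pairs=(), row_errors=None, warnings=None):
        super().__init__(pairs)
        self.row_errors: list[tuple[int, str]] = row_errors or []
        self.warnings: list[str] = warnings or []


def _read_tsv_rows(path) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="utf-8", errors="replace", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        rows = list(reader)
    if not rows:
        raise DialectError(f"{path}: empty file, no header row")
    return rows[0], rows[1:]


def read_ala_table(path, mapping: FieldMapping | None = None) -> ReadResult:
    """Read an ALA-style TSV download into paired records.

    ``_raw``-suffixed columns populate the original side, all others the
    processed side, subject to the quirks in ``mapping.known_quirks``.
    Rows with the wrong column count are collected as row errors, not fatal.
    """
    mapping = mapping or FieldMapping()
    header, rows = _read_tsv_rows(path)
    if not any(h.strip() for h in header):
        raise DialectError(f"{path}: blank header row")

    quirks = set(mapping.known_quirks)
    explicit_raw = {v: k for k, v in mapping.raw_column_for.items()}
    explicit_proc = {v: k for k, v in mapping.processed_column_for.items()}

    # (side, term) per physical column, resolved positionally.
    seen: Counter = Counter()
    columns: list[tuple[str, str]] = []
    for name in header:
        name = name.strip()
        occurrence = seen[name]
        seen[name] += 1
        if name in explicit_raw:
            columns.append(("original", explicit_raw[name]))
        elif name in explicit_proc:
            columns.append(("processed", explicit_proc[name]))
        elif name.endswith("_raw"):
            columns.append(("original", name[: -len("_raw")]))
        elif (
            name == "specificEpithet"
            and occurrence == 1
            and "second_specificEpithet_is_raw" in quirks
        ):
            columns.append(("original", "specificEpithet"))
        else:
            columns.append(("processed", name))

    id_candidates = [
        i
        for i, (side, term) in enumerate(columns)
        if side == "processed" and term in mapping.id_columns
    ]

    result = ReadResult()
    for rownum, row in enumerate(rows, start=2):
        if len(row) != len(header):
            result.row_errors.append(
                (rownum, f"expected {len(header)} columns, got {len(row)}")
            )
            continue
        original: dict[str, str] = {}
        processed: dict[str, str] = {}
        for (side, term), value in zip(columns, row):
            target = original if side == "original" else processed
            if term not in target or (not target[term].strip() and value.strip()):
                # duplicate columns collapse: first non-blank wins
                target.setdefault(term, "")
                if not target[term].strip():
                    target[term] = value
            # later duplicates ignored once a non-blank value is held
        record_id = row[id_candidates[0]] if id_candidates else str(rownum - 1)
        catalog = original.get("catalogNumber") or processed.get("catalogNumber", "")
        result.append(
            RecordPair(
                record_id=record_id,
                catalog_number=catalog.strip(),
                original=original,
                processed=processed,
                source="ALA",
            )
        )
    return result


def _parse_meta(meta_text: str) -> dict[str, str]:
    """File locations declared in meta.xml: role ('core'/'verbatim') -> filename."""
    ns = {"dwc": "http://rs.tdwg.org/dwc/text/"}
    root = ElementTree.fromstring(meta_text)
    files: dict[str, str] = {}
    core = root.find("dwc:core", ns)
    if core is not None:
        loc = core.find("dwc:files/dwc:location", ns)
        if loc is not None and loc.text:
            files["core"] = loc.text.strip()
    for ext in root.findall("dwc:extension", ns):
        loc = ext.find("dwc:files/dwc:location", ns)
        if loc is not None and loc.text:
            files.setdefault("verbatim", loc.text.strip())
    return files


def _dwca_tables(path) -> dict[str, tuple[list[str], list[list[str]]]]:
    """Return {'occurrence': (header, rows), 'verbatim': (header, rows)}."""

    def load(read_text) -> tuple[list[str], list[list[str]]]:
        reader = csv.reader(io.StringIO(read_text), delimiter="\t", quoting=csv.QUOTE_NONE)
        rows = list(reader)
        if not rows:
            raise DialectError("empty table, no header row")
        return rows[0], rows[1:]

    names = {"occurrence": "occurrence.txt", "verbatim": "verbatim.txt"}
    out: dict[str, tuple[list[str], list[list[str]]]] = {}
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            members = set(zf.namelist())
            if "meta.xml" in members:
                files = _parse_meta(zf.read("meta.xml").decode("utf-8", "replace"))
                names["occurrence"] = files.get("core", names["occurrence"])
                names["verbatim"] = files.get("verbatim", names["verbatim"])
            for role, fname in names.items():
                if fname not in members:
                    raise DialectError(f"{path}: missing {fname}")
                out[role] = load(zf.read(fname).decode("utf-8", "replace"))
    else:
        meta_path = os.path.join(path, "meta.xml")
        if os.path.exists(meta_path):
            with open(meta_path, encoding="utf-8", errors="replace") as fh:
                files = _parse_meta(fh.read())
            names["occurrence"] = files.get("core", names["occurrence"])
            names["verbatim"] = files.get("verbatim", names["verbatim"])
        for role, fname in names.items():
            fpath = os.path.join(path, fname)
            if not os.path.exists(fpath):
                raise DialectError(f"{path}: missing {fname}")
            with open(fpath, encoding="utf-8", errors="replace", newline="") as fh:
                out[role] = load(fh.read())
    return out


def read_gbif_dwca(path) -> ReadResult:
    """Read a GBIF-style Darwin Core archive (directory or zip).

    ``verbatim.txt`` rows populate the original side and are paired with the
    ``occurrence.txt`` row sharing the core id.  Ids present in exactly one
    table produce an unpaired-record warning and are excluded.
    """
    tables = _dwca_tables(path)

    def index(header, rows, label):
        id_col = 0
        if "id" in header:
            id_col = header.index("id")
        by_id: dict[str, dict[str, str]] = {}
        for row in rows:
            if len(row) != len(header):
                continue
            rid = row[id_col].strip()
            by_id.setdefault(rid, dict(zip(header, row)))
        return by_id

    verb = index(*tables["verbatim"], "verbatim")
    occ = index(*tables["occurrence"], "occurrence")

    result = ReadResult()
    for rid, vrow in verb.items():
        orow = occ.get(rid)
        if orow is None:
            result.warnings.append(f"unpaired verbatim record {rid}")
            continue
        original = {k: v for k, v in vrow.items() if k != "id"}
        processed = {k: v for k, v in orow.items() if k != "id"}
        catalog = original.get("catalogNumber") or processed.get("catalogNumber", "")
        result.append(
            RecordPair(
                record_id=rid,
                catalog_number=catalog.strip(),
                original=original,
                processed=processed,
                source="GBIF",
            )
        )
    for rid in occ.keys() - verb.keys():
        result.warnings.append(f"unpaired occurrence record {rid}")
    return result


class AlignResult(NamedTuple):
    """Join of two datasets on a shared key."""

    matched: list[tuple[RecordPair, RecordPair]]
    only_a: int
    only_b: int
    dup_a: int
    dup_b: int


def _key_value(pair: RecordPair, key: str) -> str:
    if key == "catalogNumber" and pair.catalog_number:
        return pair.catalog_number.strip()
    return (pair.original.get(key) or pair.processed.get(key) or "").strip()


def align_pairs(a, b, key: str = "catalogNumber") -> AlignResult:
    """Join two record sequences on key equality after whitespace trimming.

    Records whose key is duplicated within one input are excluded from the
    match and counted separately (``dup_a`` / ``dup_b``); blank keys never
    match.
    """

    def keyed(records):
        counts: Counter = Counter()
        by_key: dict[str, RecordPair] = {}
        for rec in records:
            k = _key_value(rec, key)
            if not k:
                continue
            counts[k] += 1
            by_key.setdefault(k, rec)
        dup_keys = {k for k, c in counts.items() if c > 1}
        dups = sum(counts[k] for k in dup_keys)
        usable = {k: v for k, v in by_key.items() if k not in dup_keys}
        return usable, dups

    ka, dup_a = keyed(a)
    kb, dup_b = keyed(b)
    shared = sorted(ka.keys() & kb.keys())
    matched = [(ka[k], kb[k]) for k in shared]
    return AlignResult(
        matched=matched,
        only_a=len(ka) - len(shared),
        only_b=len(kb) - len(shared),
        dup_a=dup_a,
        dup_b=dup_b,
    )


def _parse_modified(value: str) -> datetime | None:
    text = (value or "").strip()
    if not text:
        return None
    try:
        return datetime.fromisoformat(text)
    except ValueError:
        return None


class DedupeResult(list):
    """Deduplicated records plus bookkeeping."""

    def __init__(self, pairs=(), removed=0, flagged_groups=None):
        super().__init__(pairs)
        self.removed = removed
        self.flagged_groups: list[str] = flagged_groups or []


def dedupe_by_modified(records) -> DedupeResult:
    """Drop stale duplicate records: same ``catalogNumber``, differing
    ``modified`` timestamps — only the latest parseable version survives.
    Groups with an unparseable ``modified`` are kept intact and flagged.
    """
    groups: dict[str, list[RecordPair]] = {}
    order: list[str] = []
    for rec in records:
        k = rec.catalog_number.strip()
        if k not in groups:
            order.append(k)
        groups.setdefault(k, []).append(rec)

    result = DedupeResult()
    for k in order:
        members = groups[k]
        if len(members) == 1 or not k:
            result.extend(members)
            continue
        stamps = [
            (rec.original.get("modified") or rec.processed.get("modified") or "").strip()
            for rec in members
        ]
        if len(set(stamps)) <= 1:
            result.extend(members)  # identical timestamps: not the duplicate pattern
            continue
        parsed = [_parse_modified(s) for s in stamps]
        if any(p is None for p in parsed):
            result.extend(members)
            result.flagged_groups.append(k)
            continue
        latest = max(range(len(members)), key=lambda i: parsed[i])
        result.append(members[latest])
        result.removed += len(members) - 1
    return result


_CHANGE_COLUMNS = (
    "catalogNumber",
    "originalName",
    "processedName",
    "changeType",
    "changeDetail",
    "typeStatus",
)


def _change_row(ch: NameChange) -> tuple[str, ...]:
    return (
        ch.catalog_number,
        ch.original_name,
        ch.processed_name,
        ch.change_type.replace("_", "-"),
        ch.change_detail,
        ch.type_status,
    )


def write_change_table(changes, path, format: str = "PIPE") -> None:
    """Write a six-column change table.

    PIPE emits ``catalogNumber | original | processed | type | detail |
    typeStatus`` with single-space pipe padding (the audit's human-readable
    layout); TSV emits the same columns with a header.  Both round-trip
    losslessly through :func:`read_change_table`.
    """
    fmt = format.upper()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if fmt == "TSV":
            writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, escapechar="\\")
            writer.writerow(_CHANGE_COLUMNS)
            for ch in changes:
                writer.writerow(_change_row(ch))
        elif fmt == "PIPE":
            for ch in changes:
                fh.write(" | ".join(_change_row(ch)) + "\n")
        else:
            raise ValueError(f"unknown change-table format: {format!r}")


def read_change_table(path, format: str = "PIPE", source: str = "ALA") -> list[NameChange]:
    """Parse a change table written by :func:`write_change_table`."""
    fmt = format.upper()
    changes: list[NameChange] = []
    with open(path, encoding="utf-8", newline="") as fh:
        if fmt == "TSV":
            reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE, escapechar="\\")
            rows = list(reader)
            rows = rows[1:]  # header
        elif fmt == "PIPE":
            rows = [line.rstrip("\n").split(" | ") for line in fh if line.strip()]
        else:
            raise ValueError(f"unknown change-table format: {format!r}")
    for row in rows:
        if len(row) != 6:
            continue
        cat, orig, proc, ctype, detail, status = row
        changes.append(
            NameChange(
                catalog_number=cat,
                original_name=orig,
                processed_name=proc,
                change_type=ctype.replace("-", "_"),
                change_detail=detail,
                type_status=status,
                source=source,
            )
        )
    return changes
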