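"""Classification of taxon-name changes made by aggregator processing.

Each occurrence record contributes one original -> processed name transition.
Transitions fall into a seven-way typology:

``deleted``
    the processed name is blank — processing removed the name outright;
``fail_match``
    the name was replaced with *incertae sedis*, with a name from an
    unrelated branch of the classification (detected via kingdom/phylum
    conflict), or with a known bad match supplied via an overrides list;
``up_match`` / ``down_match``
    the name was generalised to a higher rank / particularised to a lower
    rank on the ladder;
``swap_match``
    replaced with a different name at the same rank (for ALA records this
    includes species-group names differing only in subgenus);
``subgenus``
    a subgenus was added to or deleted from a species-group name, with no
    other major change (ALA only — GBIF strips subgenera in processing, so
    its change tables carry no subgenus entries);
``amended``
    only a minor spelling/format change (per-token edit distance within a
    threshold, same initial letter).

A single processed name can embody several of these at once; records are
counted once at the highest-precedence type, with precedence
fail-match > (up-match = down-match) > swap-match > subgenus > amended.
Authorship differences and higher-classification-only differences never
count as changes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .names import RANK_LADDER, ParsedName, epithet_distance, rank_distance

__all__ = [
    "CHANGE_TYPES",
    "PRIMARY_TYPE_STATUSES",
    "ClassificationError",
    "NameChange",
    "ChangeTally",
    "AgreementReport",
    "classify_change",
    "tabulate_changes",
    "compare_aggregators",
    "type_status_crosstab",
    "load_overrides",
]

CHANGE_TYPES = (
    "none",
    "deleted",
    "fail_match",
    "up_match",
    "down_match",
    "swap_match",
    "subgenus",
    "amended",
)

#: Name-bearing type statuses, matched case-insensitively as substrings of
#: the record's ``typeStatus``.
PRIMARY_TYPE_STATUSES = frozenset({"holotype", "lectotype", "neotype", "syntype"})

_KINGDOM_INFORMAL = {
    "plantae": "plant",
    "animalia": "animal",
    "fungi": "fungus",
    "bacteria": "bacterium",
    "chromista": "chromist",
    "protista": "protist",
    "protozoa": "protozoan",
}

_LADDER_SET = frozenset(RANK_LADDER)


class ClassificationError(ValueError):
    """A name pair that cannot be classified (unresolvable rank)."""


@dataclass(frozen=True)
class NameChange:
    """One record's classified name transition."""

    catalog_number: str
    original_name: str
    processed_name: str
    change_type: str
    change_detail: str = ""
    type_status: str = ""
    source: str = "ALA"


@dataclass
class ChangeTally:
    """Record counts per (change_type, change_detail)."""

    rows: Counter = field(default_factory=Counter)
    total_changed: int = 0
    total_examined: int = 0


@dataclass
class AgreementReport:
    """Cross-aggregator agreement on which records had names changed."""

    only_a: int = 0
    both: int = 0
    only_b: int = 0
    type_matrix: Counter = field(default_factory=Counter)


def _fold(s: str) -> str:
    import unicodedata

    norm = unicodedata.normalize("NFKD", s)
    return "".join(c for c in norm if not unicodedata.combining(c)).lower()


def load_overrides(path) -> set[tuple[str, str]]:
    """Read a two-column TSV of (original canonical, processed canonical)
    pairs that must be classified fail-match (known bad matches that no
    automatic rule can spot, e.g. non-synonym same-rank replacements)."""
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 2:
                pairs.add((_fold(cols[0].strip()), _fold(cols[1].strip())))
    return pairs


def _minor(a: str, b: str, threshold: int) -> bool:
    """Token equality up to a minor spelling amendment."""
    if a == b:
        return True
    if not a or not b:
        return False
    return a[0] == b[0] and epithet_distance(a, b) <= threshold


def _higher_conflict(orig_higher, proc_higher) -> str:
    """Return the conflicting processed kingdom (folded) if the two sides
    disagree at kingdom or phylum, else ''."""
    if not orig_higher or not proc_higher:
        return ""
    for rank in ("kingdom", "phylum"):
        a = (orig_higher.get(rank) or "").strip()
        b = (proc_higher.get(rank) or "").strip()
        if a and b and _fold(a) != _fold(b):
            return _fold((proc_higher.get("kingdom") or b).strip())
    return ""


def classify_change(
    original: ParsedName,
    processed: ParsedName | None,
    orig_higher: dict[str, str] | None = None,
    proc_higher: dict[str, str] | None = None,
    overrides: set[tuple[str, str]] | None = None,
    amended_threshold: int = 2,
    source: str = "ALA",
    catalog_number: str = "",
    type_status: str = "",
) -> NameChange:
    """Classify one original -> processed name transition.

    ``original`` must be a formal genus- or species-group name (the caller
    filters; see :func:`dwcaudit.names.is_formal`).  ``processed`` may be
    ``None`` or blank, meaning the name was deleted in processing.
    Raises :class:`ClassificationError` when a rank needed for the decision
    cannot be resolved on either side.
    """
    src = source.upper()

    def result(ctype: str, detail: str) -> NameChange:
        return NameChange(
            catalog_number=catalog_number,
            original_name=original.verbatim,
            processed_name=processed.verbatim if processed else "",
            change_type=ctype,
            change_detail=detail,
            type_status=type_status,
            source=src,
        )

    # 1. deleted
    if processed is None or not processed.verbatim.strip():
        if original.rank not in _LADDER_SET:
            raise ClassificationError(f"unresolvable original rank: {original.verbatim!r}")
        return result("deleted", original.rank)

    # 2. fail-match
    proc_canon = _fold(processed.canonical or processed.verbatim).strip()
    orig_canon = _fold(original.canonical).strip()
    conflict_kingdom = _higher_conflict(orig_higher, proc_higher)
    overridden = overrides is not None and (orig_canon, proc_canon) in overrides
    if proc_canon == "incertae sedis" or conflict_kingdom or overridden:
        if original.rank not in _LADDER_SET:
            raise ClassificationError(f"unresolvable original rank: {original.verbatim!r}")
        if conflict_kingdom:
            informal = _KINGDOM_INFORMAL.get(conflict_kingdom, conflict_kingdom)
            return result("fail_match", f"{original.rank} for {informal}")
        if proc_canon == "incertae sedis":
            return result("fail_match", f"{original.rank} for incertae sedis")
        if processed.rank == original.rank:
            return result("fail_match", f"{original.rank} for {processed.rank}")
        if processed.rank in _LADDER_SET:
            return result("fail_match", f"{original.rank} to {processed.rank}")
        return result("fail_match", f"{original.rank} for unknown")

    # From here both ranks must be resolvable.
    if original.rank not in _LADDER_SET or processed.rank not in _LADDER_SET:
        raise ClassificationError(
            f"unresolvable rank: {original.verbatim!r} -> {processed.verbatim!r}"
        )

    # 3. rank changed
    d = rank_distance(original.rank, processed.rank)
    if d > 0:
        return result("up_match", f"{original.rank} to {processed.rank}")
    if d < 0:
        return result("down_match", f"{original.rank} to {processed.rank}")

    # 4.-6. same rank: compare canonical tokens
    rank = original.rank
    og, osg, osp, oin = original.canonical_tokens()
    pg, psg, psp, pin = processed.canonical_tokens()
    if src == "GBIF":
        # GBIF strips subgenera in processing; subgenus presence is ignored.
        osg = psg = ""

    core = [(og, pg), (osp, psp), (oin, pin)]
    if rank == "subgenus":
        core.append((osg, psg))

    same_rank_detail = f"{rank} for {rank}"
    if any(a != b and not _minor(a, b, amended_threshold) for a, b in core):
        return result("swap_match", same_rank_detail)

    species_group = rank in ("species", "subspecies")
    if rank != "subgenus" and osg and psg and osg != psg:
        if _minor(osg, psg, amended_threshold):
            return result("amended", same_rank_detail)
        if species_group:
            # ALA species-group names differing only in subgenus: swap-match.
            return result("swap_match", same_rank_detail)
        return result("swap_match", same_rank_detail)

    if species_group and (bool(osg) != bool(psg)):
        # Subgenus added or deleted, nothing else major: "subgenus" type.
        # Outranks "amended", so minor epithet edits ride along.
        return result("subgenus", ("added to " if psg else "deleted from ") + rank)

    if any(a != b for a, b in core):
        return result("amended", same_rank_detail)

    # Identical canonical names (authorship differences ignored).
    return result("none", "")


def tabulate_changes(changes, total_examined: int = 0) -> ChangeTally:
    """Tally records (not names) per (change_type, change_detail),
    excluding unchanged records."""
    tally = ChangeTally(total_examined=total_examined)
    for ch in changes:
        if ch.change_type == "none":
            continue
        tally.rows[(ch.change_type, ch.change_detail)] += 1
        tally.total_changed += 1
    return tally


def compare_aggregators(changes_ala, changes_gbif, matched_keys=None) -> AgreementReport:
    """Cross-tabulate which records had names changed by one aggregator,
    the other, or both, over the set of records the aggregators share."""

    def changed_by(changes):
        by_key = {}
        for ch in changes:
            if ch.change_type == "none":
                continue
            if matched_keys is not None and ch.catalog_number not in matched_keys:
                continue
            by_key.setdefault(ch.catalog_number, ch)
        return by_key

    a = changed_by(changes_ala)
    b = changed_by(changes_gbif)
    both_keys = a.keys() & b.keys()
    report = AgreementReport(
        only_a=len(a.keys() - both_keys),
        both=len(both_keys),
        only_b=len(b.keys() - both_keys),
    )
    for key in both_keys:
        report.type_matrix[(a[key].change_type, b[key].change_type)] += 1
    return report


#: Higher-classification fields read off a record when parsing names.
HIGHER_FIELDS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "superfamily",
    "family",
    "subfamily",
    "tribe",
)

_GENUS_SPECIES_GROUP = frozenset({"genus", "subgenus", "species", "subspecies"})


def _record_higher(fields: dict[str, str]) -> dict[str, str]:
    return {rank: fields.get(rank, "") for rank in HIGHER_FIELDS if fields.get(rank, "").strip()}


def classify_record(
    pair,
    overrides: set[tuple[str, str]] | None = None,
    amended_threshold: int = 2,
) -> NameChange | None:
    """Classify the name transition of one paired record.

    Returns ``None`` when the original name is informal or not in the genus
    or species group (such records are outside the audit, per the formal-name
    filter).  Raises :class:`ClassificationError` for unresolvable ranks.
    """
    from .names import is_formal, parse_scientific_name

    orig_fields, proc_fields = pair.original, pair.processed
    orig_name = orig_fields.get("scientificName", "")
    if not orig_name.strip():
        return None
    original = parse_scientific_name(
        orig_name,
        declared_rank=orig_fields.get("taxonRank"),
        higher_genus=orig_fields.get("genus"),
        higher_taxa=_record_higher(orig_fields),
    )
    if not is_formal(original) or original.rank not in _GENUS_SPECIES_GROUP:
        return None
    proc_name = proc_fields.get("scientificName", "")
    processed = None
    if proc_name.strip():
        processed = parse_scientific_name(
            proc_name,
            declared_rank=proc_fields.get("taxonRank"),
            higher_genus=proc_fields.get("genus"),
            higher_taxa=_record_higher(proc_fields),
        )
    return classify_change(
        original,
        processed,
        orig_higher=_record_higher(orig_fields),
        proc_higher=_record_higher(proc_fields),
        overrides=overrides,
        amended_threshold=amended_threshold,
        source=getattr(pair, "source", "ALA"),
        catalog_number=getattr(pair, "catalog_number", ""),
        type_status=orig_fields.get("typeStatus", ""),
    )


@dataclass
class RecordAuditResult:
    """Outcome of classifying every record of a dataset."""

    changes: list = field(default_factory=list)  # NameChange with type != none
    unchanged: int = 0
    examined: int = 0
    informal_or_out_of_scope: int = 0
    errors: list = field(default_factory=list)  # (catalog_number, message)


def audit_records(
    pairs,
    overrides: set[tuple[str, str]] | None = None,
    amended_threshold: int = 2,
) -> RecordAuditResult:
    """Run :func:`classify_record` over a dataset, collecting errors."""
    result = RecordAuditResult()
    for pair in pairs:
        try:
            change = classify_record(pair, overrides=overrides, amended_threshold=amended_threshold)
        except ClassificationError as exc:
            result.examined += 1
            result.errors.append((getattr(pair, "catalog_number", ""), str(exc)))
            continue
        if change is None:
            result.informal_or_out_of_scope += 1
            continue
        result.examined += 1
        if change.change_type == "none":
            result.unchanged += 1
        else:
            result.changes.append(change)
    return result


def type_status_crosstab(changes, primary_types=PRIMARY_TYPE_STATUSES) -> Counter:
    """Count changed records of primary type specimens per change type.

    ``primary_types`` entries are matched case-insensitively as substrings
    of the verbatim ``typeStatus`` (so "Holotype of Aus bus" counts).
    """
    wanted = {t.lower() for t in primary_types}
    counts: Counter = Counter()
    for ch in changes:
        if ch.change_type == "none":
            continue
        status = (ch.type_status or "").lower()
        if any(t in status for t in wanted):
            counts[ch.change_type] += 1
    return counts
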