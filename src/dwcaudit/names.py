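"""Parsing of Darwin Core scientific-name strings.

Occurrence records carry taxon names as free strings (``scientificName``),
optionally with a declared ``taxonRank`` and higher-classification fields.
This module splits such strings into genus / subgenus / epithets / authorship,
infers a rank on a fixed zoological ladder, and flags informal names
(manuscript names, "sp.", "cf." and similar) so that downstream change
classification can restrict itself to formal genus- and species-group names.

Conventions handled: uninomials (``Oliva``, ``Aplacophora``), genus-subgenus
pairs (``Arrenurus (Arrenurus)``), binomials and trinomials, each with
optional authorship either bare (``Lea``), comma-year (``Fruhstorfer, 1911``)
or parenthesised (``(Iredale, 1943)``).  A parenthesised group directly after
the genus that is a single capitalised word with no comma-year is read as a
subgenus; any parenthesised group containing a comma-year is authorship.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

import edlib

__all__ = [
    "RANK_LADDER",
    "ParsedName",
    "parse_scientific_name",
    "is_formal",
    "rank_distance",
    "epithet_distance",
    "DEFAULT_INFORMAL_PATTERNS",
]

#: Ranks from most general to most specific.  Superfamily/subfamily/tribe sit
#: between order/family/genus, matching the change-detail vocabulary used in
#: the audit tallies ("species to tribe", "genus to subfamily", ...).
RANK_LADDER: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "superfamily",
    "family",
    "subfamily",
    "tribe",
    "genus",
    "subgenus",
    "species",
    "subspecies",
)

_RANK_INDEX = {r: i for i, r in enumerate(RANK_LADDER)}

#: Markers that make a name string informal.  Matched case-insensitively
#: against the whole name.  The set is configurable: pass a replacement list
#: to :func:`parse_scientific_name` / :func:`is_formal`.
DEFAULT_INFORMAL_PATTERNS: tuple[str, ...] = (
    r"\bn\s*\.\s*sp\b",      # n.sp., n. sp.
    r"\bsp\b\.?(?!\w)",      # sp., sp
    r"\bspp\b\.?",
    r"\baff\b\.?",
    r"\bcf\b\.?",
    r"\bindet\b\.?",
    r"\d",                   # digits anywhere
    r"_",
    r"\?",
)

_COMMA_YEAR = re.compile(r",\s*\(?\d{4}\)?")
_EPITHET = re.compile(r"^[a-z][a-z\-]+$")
_CAPWORD = re.compile(r"^[A-Z][a-zA-Z\-]+$")


def _fold(s: str) -> str:
    """Lowercase and strip diacritics, for comparison only."""
    norm = unicodedata.normalize("NFKD", s)
    return "".join(c for c in norm if not unicodedata.combining(c)).lower()


@dataclass(frozen=True)
class ParsedName:
    """A scientific name split into nomenclatural components.

    ``canonical`` is the name without authorship, with the subgenus in
    parentheses when present.  ``rank`` is one of :data:`RANK_LADDER`,
    ``"uninomial_above_genus"`` for an above-genus uninomial whose exact
    level could not be pinned down, or ``"unknown"``.
    """

    genus: str = ""
    subgenus: str = ""
    specific_epithet: str = ""
    infraspecific_epithet: str = ""
    authorship: str = ""
    rank: str = "unknown"
    formal: bool = False
    canonical: str = ""
    verbatim: str = field(default="", compare=False)

    def canonical_tokens(self) -> tuple[str, str, str, str]:
        """(genus, subgenus, specific, infraspecific), diacritic-folded."""
        return (
            _fold(self.genus),
            _fold(self.subgenus),
            _fold(self.specific_epithet),
            _fold(self.infraspecific_epithet),
        )


def _render_canonical(genus: str, subgenus: str, sp: str, infra: str) -> str:
    parts = [genus]
    if subgenus:
        parts.append(f"({subgenus})")
    if sp:
        parts.append(sp)
    if infra:
        parts.append(infra)
    return " ".join(p for p in parts if p)


def _matches_informal(name: str, patterns) -> bool:
    return any(re.search(p, name, flags=re.IGNORECASE) for p in patterns)


def _uninomial_rank(
    name: str,
    declared_rank: str | None,
    higher_genus: str | None,
    higher_taxa: dict[str, str] | None,
) -> str:
    """Rank of a lone capitalised word, using whatever context the record has."""
    folded = _fold(name)
    if higher_genus and _fold(higher_genus) == folded:
        return "genus"
    if higher_taxa:
        # Scan most-specific first so e.g. a family homonymous with an order
        # resolves to family.
        for rank in reversed(RANK_LADDER):
            value = higher_taxa.get(rank, "")
            if value and _fold(value) == folded:
                return rank
    if declared_rank:
        dr = declared_rank.strip().lower()
        if dr in _RANK_INDEX and dr not in ("species", "subspecies"):
            return dr
    if higher_genus or higher_taxa:
        # Context was given and the uninomial matched none of it: it is not
        # the record's genus, so it sits somewhere above genus.
        return "uninomial_above_genus"
    return "uninomial_above_genus"


def parse_scientific_name(
    name: str,
    declared_rank: str | None = None,
    higher_genus: str | None = None,
    higher_taxa: dict[str, str] | None = None,
    informal_patterns=DEFAULT_INFORMAL_PATTERNS,
) -> ParsedName:
    """Parse a scientificName string into a :class:`ParsedName`.

    Parameters
    ----------
    name:
        The verbatim name string; blank is allowed and yields an informal,
        rank-unknown result.
    declared_rank:
        The record's Darwin Core ``taxonRank``, honoured when consistent with
        the parsed structure (a binomial stays ``species`` whatever is
        declared; a uninomial may be pinned to any above-species rank).
    higher_genus:
        The record's ``genus`` field, used to recognise genus uninomials.
    higher_taxa:
        Map of rank -> name from the record's higher-classification fields,
        used to pin the rank of above-genus uninomials.

    Unparseable strings never raise; they come back with ``formal=False``
    and ``rank="unknown"``.
    """
    verbatim = name or ""
    text = re.sub(r"\s+", " ", verbatim).strip()
    if not text:
        return ParsedName(verbatim=verbatim)

    genus = subgenus = sp = infra = ""
    authorship_parts: list[str] = []
    irregular = False

    # Parenthesised groups are subgenus or authorship; a comma-year inside
    # the parentheses means authorship.
    raw_tokens = text.split(" ")
    i = 0
    n = len(raw_tokens)

    def take_rest_as_authorship(j: int) -> None:
        authorship_parts.extend(raw_tokens[j:])

    # genus / leading uninomial
    if not _CAPWORD.match(raw_tokens[0]):
        return ParsedName(formal=False, rank="unknown", canonical=text, verbatim=verbatim)
    genus = raw_tokens[0]
    i = 1

    # optional (Subgenus) — single capitalised word, no comma-year
    if i < n and raw_tokens[i].startswith("("):
        # gather up to closing paren
        j = i
        group = []
        while j < n:
            group.append(raw_tokens[j])
            if raw_tokens[j].endswith(")"):
                break
            j += 1
        group_text = " ".join(group)
        inner = group_text.strip("()")
        if not group_text.endswith(")"):
            irregular = True
            i = j + 1
        elif _COMMA_YEAR.search(group_text):
            authorship_parts.append(group_text)
            take_rest_as_authorship(j + 1)
            i = n
        elif _CAPWORD.match(inner) and len(group) == 1:
            subgenus = inner
            i = j + 1
        else:
            irregular = True
            i = j + 1

    # epithets (lowercase tokens), then authorship from the first capitalised
    # or parenthesised token after the lowest epithet
    while i < n and not authorship_parts:
        tok = raw_tokens[i]
        if _EPITHET.match(tok):
            if not sp:
                sp = tok
            elif not infra:
                infra = tok
            else:
                irregular = True  # quadrinomial or worse
            i += 1
        elif tok.startswith("(") or tok[0].isupper():
            take_rest_as_authorship(i)
            i = n
        else:
            # lowercase token that is not a plausible epithet (e.g. "sect.")
            irregular = True
            i += 1

    authorship = " ".join(authorship_parts)

    # Rank inference
    if irregular:
        rank = "unknown"
    elif infra:
        rank = "subspecies"
    elif sp:
        rank = "species"
    elif subgenus:
        rank = "subgenus"
    else:
        rank = _uninomial_rank(genus, declared_rank, higher_genus, higher_taxa)

    # declared_rank override where consistent with the structure
    if declared_rank and not irregular:
        dr = declared_rank.strip().lower()
        if dr in _RANK_INDEX:
            structure_ok = (
                (dr == "species" and sp and not infra)
                or (dr == "subspecies" and infra)
                or (dr == "subgenus" and subgenus and not sp)
                or (_RANK_INDEX[dr] < _RANK_INDEX["subgenus"] and not sp and not subgenus)
            )
            if structure_ok:
                rank = dr

    canonical = _render_canonical(genus, subgenus, sp, infra) if not irregular else (
        _COMMA_YEAR.sub("", text) if not authorship else text.replace(authorship, "").strip()
    )
    # Informal markers are judged on the name proper; years and question
    # marks inside the authorship do not make a name informal.
    informal = _matches_informal(canonical, informal_patterns)
    formal = not informal and not irregular and rank != "unknown"
    return ParsedName(
        genus=genus,
        subgenus=subgenus,
        specific_epithet=sp,
        infraspecific_epithet=infra,
        authorship=authorship,
        rank=rank,
        formal=formal,
        canonical=canonical,
        verbatim=verbatim,
    )


def is_formal(p: ParsedName, informal_patterns=DEFAULT_INFORMAL_PATTERNS) -> bool:
    """True when the name is a formal scientific name.

    False for blank/unparseable names (``rank == "unknown"``) and for names
    carrying informal markers (``n.sp.``, ``sp.``, ``cf.``, digits,
    underscores, question marks — the marker set is configurable).
    """
    if p.rank == "unknown":
        return False
    if p.canonical and _matches_informal(p.canonical, informal_patterns):
        return False
    return p.formal


def rank_distance(a: str, b: str, ladder: tuple[str, ...] = RANK_LADDER) -> int:
    """Signed ladder distance: positive when ``b`` is more general than ``a``.

    Zero iff the ranks are equal.  Raises ``ValueError`` for ranks not on the
    ladder (``unknown``, ``uninomial_above_genus``).
    """
    try:
        ia, ib = ladder.index(a), ladder.index(b)
    except ValueError as exc:
        raise ValueError(f"rank not on ladder: {a!r} vs {b!r}") from exc
    return ia - ib


def epithet_distance(a: str, b: str) -> int:
    """Levenshtein edit distance between two name tokens, case-folded."""
    fa, fb = _fold(a), _fold(b)
    if fa == fb:
        return 0
    if not fa or not fb:
        return max(len(fa), len(fb))
    return edlib.align(fa, fb, task="distance")["editDistance"]
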