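"""Synthetic paired occurrence datasets with a ground-truth defect manifest.

The generator emulates the structure of an aggregator download: for every
record it produces an *original* (as-supplied) field map and a *processed*
field map, then injects a requested number of each defect class — name
changes built as the inverse of the classifier's definitions, date-format /
outcome combinations, agent-string corruption patterns, datum mapping
errors, per-field data loss, stale duplicate rows and country mismatches.
The returned :class:`SyntheticManifest` records exactly what was injected,
so a full pipeline run over the generated dataset must recover it — the
recovery test that anchors the whole package.

Defects are disjoint: each record carries at most one injected defect, so
audit tallies partition cleanly.  A single ``random.Random`` stream keyed by
the seed drives all draws in a fixed order (taxonomy, base records, then
defect families in alphabetical order), making fixtures byte-identical for
identical (seed, spec).

Taxon names are built from alternating consonant-vowel syllables, which
keeps them parseable and clear of informal-name markers.  The toy taxonomy
always contains at least two kingdoms — the first is ``Animalia`` (all base
records), the second ``Plantae`` (the donor for cross-kingdom
fail-matches).
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

from .dwc_io import RecordPair

__all__ = [
    "SyntheticManifest",
    "ToyTaxonomy",
    "ToySpecies",
    "SyntheticDataset",
    "InfeasibleSpecError",
    "generate_taxonomy",
    "generate_paired_dataset",
    "write_fixture",
    "example_study_spec",
    "DEFAULT_FANOUT",
]

DEFAULT_FANOUT = {
    "kingdom": 2,
    "phylum": 2,
    "class": 2,
    "order": 2,
    "family": 2,
    "genus": 2,
    "species": 3,
}

_KINGDOM_NAMES = ("Animalia", "Plantae", "Fungi", "Chromista")

_CONSONANTS = "bdglmnprstvz"
_VOWELS = "aeiou"


class InfeasibleSpecError(ValueError):
    """The requested defect counts cannot be realised."""


@dataclass
class SyntheticManifest:
    """Ground-truth counts of every injected defect.

    ``name_change_counts`` keys are (change_type, change_detail) pairs;
    ``date_outcome_counts`` keys are (format_class, outcome) pairs.  The
    realized manifest returned by :func:`generate_paired_dataset` also fills
    in the baseline counts the audits will see (e.g. ``unchanged`` agents,
    ``correct`` datums), so summaries over the dataset match it exactly.
    """

    seed: int = 0
    n_records: int = 100
    name_change_counts: dict = field(default_factory=dict)
    date_outcome_counts: dict = field(default_factory=dict)
    agent_pattern_counts: dict = field(default_factory=dict)
    datum_verdict_counts: dict = field(default_factory=dict)
    field_loss_counts: dict = field(default_factory=dict)
    duplicate_pairs: int = 0
    country_mismatches: int = 0

    def total_injected(self) -> int:
        return (
            sum(self.name_change_counts.values())
            + sum(self.date_outcome_counts.values())
            + sum(v for k, v in self.agent_pattern_counts.items() if k != "unchanged")
            + sum(v for k, v in self.datum_verdict_counts.items() if k != "correct")
            + sum(self.field_loss_counts.values())
            + self.country_mismatches
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_records": self.n_records,
            "name_change_counts": {
                f"{t}|{d}": c for (t, d), c in sorted(self.name_change_counts.items())
            },
            "date_outcome_counts": {
                f"{fc}|{o}": c for (fc, o), c in sorted(self.date_outcome_counts.items())
            },
            "agent_pattern_counts": dict(sorted(self.agent_pattern_counts.items())),
            "datum_verdict_counts": dict(sorted(self.datum_verdict_counts.items())),
            "field_loss_counts": dict(sorted(self.field_loss_counts.items())),
            "duplicate_pairs": self.duplicate_pairs,
            "country_mismatches": self.country_mismatches,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticManifest":
        known = {
            "seed",
            "n_records",
            "name_change_counts",
            "date_outcome_counts",
            "agent_pattern_counts",
            "datum_verdict_counts",
            "field_loss_counts",
            "duplicate_pairs",
            "country_mismatches",
        }
        unknown = set(data) - known
        if unknown:
            raise InfeasibleSpecError(f"unknown manifest keys: {sorted(unknown)}")
        m = cls()
        m.seed = int(data.get("seed", 0))
        m.n_records = int(data.get("n_records", 100))
        m.name_change_counts = {
            tuple(k.split("|", 1)): int(v)
            for k, v in (data.get("name_change_counts") or {}).items()
        }
        m.date_outcome_counts = {
            tuple(k.split("|", 1)): int(v)
            for k, v in (data.get("date_outcome_counts") or {}).items()
        }
        m.agent_pattern_counts = {
            k: int(v) for k, v in (data.get("agent_pattern_counts") or {}).items()
        }
        m.datum_verdict_counts = {
            k: int(v) for k, v in (data.get("datum_verdict_counts") or {}).items()
        }
        m.field_loss_counts = {
            k: int(v) for k, v in (data.get("field_loss_counts") or {}).items()
        }
        m.duplicate_pairs = int(data.get("duplicate_pairs", 0))
        m.country_mismatches = int(data.get("country_mismatches", 0))
        return m


@dataclass(frozen=True)
class ToySpecies:
    """One species leaf with its full rank path and helper names."""

    kingdom: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    epithet: str
    alt_epithet: str  # different initial letter: a guaranteed swap
    authorship: str

    def higher(self) -> dict[str, str]:
        return {
            "kingdom": self.kingdom,
            "phylum": self.phylum,
            "class": self.class_,
            "order": self.order,
            "family": self.family,
        }

    def binomial(self) -> str:
        return f"{self.genus} {self.epithet}"


@dataclass
class ToyTaxonomy:
    """A small ranked tree; every species leaf has a complete rank path."""

    fanout: dict
    species: list = field(default_factory=list)

    def by_kingdom(self, kingdom: str) -> list:
        return [s for s in self.species if s.kingdom == kingdom]

    @property
    def kingdoms(self) -> list[str]:
        seen = []
        for s in self.species:
            if s.kingdom not in seen:
                seen.append(s.kingdom)
        return seen


def _word(rng: random.Random, syllables: int) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(syllables))


def _unique_word(rng: random.Random, used: set, syllables: int, capital: bool) -> str:
    for attempt in range(200):
        w = _word(rng, syllables + (attempt // 50))
        w = w.capitalize() if capital else w
        if w not in used:
            used.add(w)
            return w
    raise RuntimeError("name space exhausted")  # pragma: no cover


def _word_with_other_initial(rng: random.Random, used: set, syllables: int, avoid_initial: str,
                             capital: bool) -> str:
    while True:
        w = _unique_word(rng, used, syllables, capital)
        if w[0].lower() != avoid_initial.lower():
            return w
        used.discard(w)


def generate_taxonomy(seed: int, fanout: dict | None = None) -> ToyTaxonomy:
    """Build a deterministic toy taxonomy with the given per-rank fan-out.

    Fan-out must be >= 1 at every rank; the same seed always yields the
    identical tree.  Kingdoms take real names (Animalia, Plantae, ...) so
    cross-kingdom fail-matches carry the field's usual vocabulary.
    """
    fanout = dict(DEFAULT_FANOUT, **(fanout or {}))
    if any(v < 1 for v in fanout.values()):
        raise ValueError("fanout must be >= 1 at every rank")
    rng = random.Random(seed)
    used: dict[str, set] = {r: set() for r in fanout}
    tax = ToyTaxonomy(fanout=fanout)
    n_kingdoms = max(fanout["kingdom"], 2)
    for ki in range(n_kingdoms):
        kingdom = (
            _KINGDOM_NAMES[ki] if ki < len(_KINGDOM_NAMES)
            else _unique_word(rng, used["kingdom"], 4, True)
        )
        for _ in range(fanout["phylum"]):
            phylum = _unique_word(rng, used["phylum"], 3, True)
            for _ in range(fanout["class"]):
                cls = _unique_word(rng, used["class"], 3, True)
                for _ in range(fanout["order"]):
                    order = _unique_word(rng, used["order"], 3, True)
                    for _ in range(fanout["family"]):
                        family = _unique_word(rng, used["family"], 3, True) + "idae"
                        for _ in range(fanout["genus"]):
                            genus = _unique_word(rng, used["genus"], 3, True)
                            used.setdefault("species", set())
                            for _ in range(fanout["species"]):
                                epithet = _unique_word(rng, used["species"], 3, False)
                                alt = _word_with_other_initial(
                                    rng, used["species"], 3, epithet[0], False
                                )
                                author = f"{_word(rng, 2).capitalize()}, {rng.randint(1800, 1999)}"
                                tax.species.append(
                                    ToySpecies(
                                        kingdom=kingdom,
                                        phylum=phylum,
                                        class_=cls,
                                        order=order,
                                        family=family,
                                        genus=genus,
                                        epithet=epithet,
                                        alt_epithet=alt,
                                        authorship=author,
                                    )
                                )
    return tax


@dataclass
class SyntheticDataset:
    """Generated paired tables plus the realized ground-truth manifest."""

    pairs: list = field(default_factory=list)  # RecordPair, duplicates included
    manifest: SyntheticManifest = field(default_factory=SyntheticManifest)
    dialect: str = "ALA_TSV"

    @property
    def original_rows(self) -> list[dict]:
        return [p.original for p in self.pairs]

    @property
    def processed_rows(self) -> list[dict]:
        return [p.processed for p in self.pairs]


_BASE_TERMS = (
    "catalogNumber",
    "scientificName",
    "scientificNameAuthorship",
    "taxonRank",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "specificEpithet",
    "infraspecificEpithet",
    "typeStatus",
    "eventDate",
    "recordedBy",
    "identifiedBy",
    "locality",
    "habitat",
    "geodeticDatum",
    "country",
    "basisOfRecord",
    "modified",
)


def _base_record(i: int, sp: ToySpecies, rng: random.Random, dialect: str) -> RecordPair:
    with_author = rng.random() < 0.5
    name = sp.binomial() + (f" {sp.authorship}" if with_author else "")
    surname = _word(rng, 3).capitalize()
    recorder = f"{surname}, {rng.choice('ABDEGJKLMNPRSTW')}."
    original = {
        "catalogNumber": f"C.{100000 + i}",
        "scientificName": name,
        "scientificNameAuthorship": sp.authorship if with_author else "",
        "taxonRank": "species",
        "kingdom": sp.kingdom,
        "phylum": sp.phylum,
        "class": sp.class_,
        "order": sp.order,
        "family": sp.family,
        "genus": sp.genus,
        "specificEpithet": sp.epithet,
        "infraspecificEpithet": "",
        "typeStatus": "",
        "eventDate": "",
        "recordedBy": recorder,
        "identifiedBy": recorder,
        "locality": f"Site {100000 + i}",
        "habitat": f"habitat {100000 + i}",
        "geodeticDatum": "WGS84",
        "country": "Australia",
        "basisOfRecord": "PreservedSpecimen",
        "modified": "2017-05-09T10:00:00+12:00",
    }
    processed = dict(original)
    processed["scientificName"] = sp.binomial()  # authorship stripped in processing
    processed["geodeticDatum"] = "EPSG:4326"
    if dialect == "GBIF_DWCA":
        del processed["scientificNameAuthorship"]
        del processed["country"]
        processed["countryCode"] = "AU"
    return RecordPair(
        record_id=f"r{i:06d}",
        catalog_number=original["catalogNumber"],
        original=original,
        processed=processed,
        source="ALA" if dialect == "ALA_TSV" else "GBIF",
        dataset_tag="SYN",
    )


def _set_original_name(pair: RecordPair, name: str, rank: str, genus: str = "",
                       epithet: str = "", infra: str = "") -> None:
    pair.original["scientificName"] = name
    pair.original["taxonRank"] = rank
    pair.original["genus"] = genus
    pair.original["specificEpithet"] = epithet
    pair.original["infraspecificEpithet"] = infra


def _set_processed_name(pair: RecordPair, name: str, rank: str = "", genus: str | None = None,
                        higher: dict | None = None) -> None:
    pair.processed["scientificName"] = name
    if rank:
        pair.processed["taxonRank"] = rank
    if genus is not None:
        pair.processed["genus"] = genus
    for field_name, value in (higher or {}).items():
        pair.processed[field_name] = value


class _NameInjector:
    """Applies one (change_type, change_detail) construction to a record."""

    def __init__(self, taxonomy: ToyTaxonomy, rng: random.Random, dialect: str):
        self.tax = taxonomy
        self.rng = rng
        self.dialect = dialect
        self.used_names: set = set()
        donors = taxonomy.by_kingdom("Plantae")
        if not donors:  # pragma: no cover - taxonomy always has Plantae
            donors = [s for s in taxonomy.species if s.kingdom != taxonomy.kingdoms[0]]
        self.plant_pool = donors

    def apply(self, ctype: str, detail: str, pair: RecordPair, sp: ToySpecies) -> None:
        gbif = self.dialect == "GBIF_DWCA"
        words = detail.split()
        if ctype == "deleted":
            rank = detail.strip()
            self._shape_original(pair, sp, rank)
            _set_processed_name(pair, "", rank="")
            return
        if ctype == "fail_match":
            if detail == "species for plant":
                donor = self.rng.choice(self.plant_pool)
                _set_processed_name(
                    pair, donor.binomial(), rank="species", genus=donor.genus,
                    higher={"kingdom": donor.kingdom, "phylum": donor.phylum,
                            "class": donor.class_, "order": donor.order,
                            "family": donor.family},
                )
                return
            if detail == "species for incertae sedis":
                _set_processed_name(pair, "incertae sedis", rank="")
                return
            raise InfeasibleSpecError(f"unsupported fail_match detail: {detail!r}")
        if ctype in ("up_match", "down_match") and len(words) == 3 and words[1] == "to":
            src_rank, dst_rank = words[0], words[2]
            self._shape_original(pair, sp, src_rank)
            self._shape_processed(pair, sp, dst_rank)
            return
        if ctype == "swap_match" and len(words) == 3 and words[1] == "for" and words[0] == words[2]:
            rank = words[0]
            self._shape_original(pair, sp, rank)
            if rank == "species":
                _set_processed_name(pair, f"{sp.genus} {sp.alt_epithet}", rank="species")
            elif rank == "subspecies":
                self._shape_processed_trinomial(pair, sp, sp.alt_epithet)
            elif rank == "genus":
                other = _word_with_other_initial(
                    self.rng, self.used_names, 3, sp.genus[0], True
                )
                _set_processed_name(pair, other, rank="genus", genus=other)
            elif rank == "subgenus":
                if gbif:
                    raise InfeasibleSpecError(
                        "subgenus-rank names are stripped in the GBIF dialect"
                    )
                other = _word_with_other_initial(
                    self.rng, self.used_names, 3, sp.genus[0], True
                )
                _set_processed_name(pair, f"{sp.genus} ({other})", rank="subgenus")
            else:
                raise InfeasibleSpecError(f"unsupported swap_match detail: {detail!r}")
            return
        if ctype == "subgenus":
            if gbif:
                raise InfeasibleSpecError("subgenus changes are ALA-only (GBIF strips subgenera)")
            if detail == "added to species":
                _set_processed_name(pair, f"{sp.genus} ({sp.genus}) {sp.epithet}", rank="species")
                return
            if detail == "deleted from species":
                _set_original_name(
                    pair, f"{sp.genus} ({sp.genus}) {sp.epithet}", "species",
                    genus=sp.genus, epithet=sp.epithet,
                )
                _set_processed_name(pair, sp.binomial(), rank="species")
                return
            raise InfeasibleSpecError(f"unsupported subgenus detail: {detail!r}")
        if ctype == "amended" and len(words) == 3 and words[1] == "for" and words[0] == words[2]:
            rank = words[0]
            self._shape_original(pair, sp, rank)
            if rank == "species":
                _set_processed_name(pair, f"{sp.genus} {_amend(sp.epithet)}", rank="species")
            elif rank == "subspecies":
                self._shape_processed_trinomial(pair, sp, _amend(sp.epithet))
            elif rank == "genus":
                g = _amend(sp.genus)
                _set_processed_name(pair, g, rank="genus", genus=g)
            else:
                raise InfeasibleSpecError(f"unsupported amended detail: {detail!r}")
            return
        raise InfeasibleSpecError(f"unsupported name change: {ctype!r} {detail!r}")

    def _shape_original(self, pair: RecordPair, sp: ToySpecies, rank: str) -> None:
        if rank == "species":
            pass  # base record is already a species binomial
        elif rank == "subspecies":
            _set_original_name(
                pair, f"{sp.genus} {sp.epithet} {sp.epithet}", "subspecies",
                genus=sp.genus, epithet=sp.epithet, infra=sp.epithet,
            )
        elif rank == "genus":
            _set_original_name(pair, sp.genus, "genus", genus=sp.genus)
        elif rank == "subgenus":
            if self.dialect == "GBIF_DWCA":
                raise InfeasibleSpecError("subgenus-rank originals unsupported in GBIF dialect")
            _set_original_name(pair, f"{sp.genus} ({sp.genus})", "subgenus", genus=sp.genus)
        else:
            raise InfeasibleSpecError(f"original rank {rank!r} not in the genus/species group")

    def _shape_processed(self, pair: RecordPair, sp: ToySpecies, rank: str) -> None:
        higher = sp.higher()
        if rank == "species":
            _set_processed_name(pair, sp.binomial(), rank="species")
        elif rank == "subspecies":
            self._shape_processed_trinomial(pair, sp, sp.epithet)
        elif rank == "genus":
            _set_processed_name(pair, sp.genus, rank="genus", genus=sp.genus)
        elif rank == "subgenus":
            if self.dialect == "GBIF_DWCA":
                raise InfeasibleSpecError("subgenus targets unsupported in GBIF dialect")
            _set_processed_name(pair, f"{sp.genus} ({sp.genus})", rank="subgenus", genus=sp.genus)
        elif rank in higher:
            _set_processed_name(pair, higher[rank], rank=rank, higher={rank: higher[rank]})
        else:
            raise InfeasibleSpecError(f"target rank {rank!r} absent from the toy taxonomy")

    def _shape_processed_trinomial(self, pair: RecordPair, sp: ToySpecies, infra: str) -> None:
        _set_processed_name(
            pair, f"{sp.genus} {sp.epithet} {infra}", rank="subspecies"
        )


def _amend(token: str) -> str:
    """Minor spelling change: same initial, edit distance 1, never equal."""
    last = token[-1]
    replacement = "a" if last != "a" else "u"
    return token[:-1] + replacement


_DATE_RAW = {
    "Y": "1987",
    "YM": "1987-06",
    "YMD": "1985-10-06",
    "YMD_loose": "1985-1-6",
    "INTERVAL_DD": "1943-06-20/21",
    "INTERVAL_MD": "1943-06-20/07-02",
    "INTERVAL_YMD": "1943-06-20/1943-06-25",
    "INTERVAL_Y": "1943-06-20/1944",
    "INTERVAL_YM": "1943-06-20/1943-08",
    "DATETIME_TZ": "2017-05-09T10:00:00+12:00",
    "DATETIME_FRAC_TZ": "2017-05-09T10:00:00.000+12:00",
    "MALFORMED": "2006-09-02/2005-11-20",
}

_INTERVAL_STARTS = {
    "INTERVAL_DD": "1943-06-20",
    "INTERVAL_MD": "1943-06-20",
    "INTERVAL_YMD": "1943-06-20",
    "INTERVAL_Y": "1943-06-20",
    "INTERVAL_YM": "1943-06-20",
}


def _inject_date(pair: RecordPair, format_class: str, outcome: str) -> None:
    raw = _DATE_RAW.get(format_class)
    if raw is None:
        raise InfeasibleSpecError(f"unknown date format class {format_class!r}")
    if outcome == "excluded":
        if format_class == "MALFORMED":
            raise InfeasibleSpecError("a MALFORMED raw date cannot count as excluded")
        processed = ""
    elif outcome == "accepted_start_only":
        start = _INTERVAL_STARTS.get(format_class)
        if start is None:
            raise InfeasibleSpecError(
                f"accepted_start_only needs an interval class, not {format_class!r}"
            )
        processed = start
    elif outcome == "accepted_full":
        if format_class == "MALFORMED":
            raise InfeasibleSpecError("a MALFORMED raw date cannot count as accepted_full")
        processed = raw
    elif outcome == "altered":
        processed = "1900-01-01"
    elif outcome == "not_applicable":
        if format_class != "MALFORMED":
            raise InfeasibleSpecError("not_applicable applies only to MALFORMED raw dates")
        processed = ""
    else:
        raise InfeasibleSpecError(f"unknown date outcome {outcome!r}")
    pair.original["eventDate"] = raw
    pair.processed["eventDate"] = processed


def _inject_agent(pair: RecordPair, pattern: str, rng: random.Random) -> None:
    sur = _word(rng, 3).capitalize()
    sur2 = _word(rng, 3).capitalize()
    while sur2 == sur:  # distinct surnames keep each pattern unambiguous
        sur2 = _word(rng, 3).capitalize()
    first = _word(rng, 2).capitalize()
    if pattern == "null_replacement":
        raw = f"A.{sur} & E.{sur2}"
        processed = f"{sur}, A.|null"
    elif pattern == "conjunction_failure":
        raw = f"J.{sur} & G.{sur2}"
        processed = f"{sur2}, J.|{sur2}, G."
    elif pattern == "initial_reversal":
        raw = f"{sur}, {first} S."
        processed = f"{sur}, S. {first}"
    elif pattern == "added_initial":
        raw = f"{sur}, {first}"
        processed = f"{sur}, {first[0]}. {first}"
    elif pattern == "initial_comma":
        raw = "B.M.R."
        processed = ", B.M.R."
    elif pattern == "surname_ending_truncation":
        raw = f"M. {sur}and"
        processed = f"{sur}, M.|"
    elif pattern == "changed_ok":
        raw = f"J.& D.{sur}"
        processed = f"{sur}, J.|{sur}, D."
    else:
        raise InfeasibleSpecError(f"unknown agent pattern {pattern!r}")
    pair.original["recordedBy"] = raw
    pair.processed["recordedBy"] = processed


def _inject_datum(pair: RecordPair, verdict: str) -> None:
    if verdict == "incorrect_mapping":
        pair.original["geodeticDatum"] = "AGD66"
        pair.processed["geodeticDatum"] = "EPSG:4326"
    elif verdict == "deleted":
        pair.processed["geodeticDatum"] = ""
    elif verdict == "unmapped":
        pair.original["geodeticDatum"] = "LOCALGRID1"
        pair.processed["geodeticDatum"] = "EPSG:4326"
    elif verdict == "correct":
        pass  # the baseline already maps WGS84 -> EPSG:4326
    else:
        raise InfeasibleSpecError(f"unknown datum verdict {verdict!r}")


def generate_paired_dataset(
    manifest_spec: SyntheticManifest,
    taxonomy: ToyTaxonomy | None = None,
    dialect: str = "ALA_TSV",
    type_status_for_changes: str = "",
) -> SyntheticDataset:
    """Generate a paired original/processed dataset realising a defect spec.

    Every requested defect lands on a distinct record; infeasible specs
    (counts exceeding ``n_records``, constructions the dialect forbids,
    unknown defect labels) raise :class:`InfeasibleSpecError` before any
    record is built.  When ``type_status_for_changes`` is set (e.g.
    ``"Holotype"``), records receiving a name change carry it in
    ``typeStatus``, so type-status crosstabs are manifest-predictable.
    """
    spec = manifest_spec
    if dialect not in ("ALA_TSV", "GBIF_DWCA"):
        raise InfeasibleSpecError(f"unknown dialect {dialect!r}")
    if spec.total_injected() > spec.n_records:
        raise InfeasibleSpecError(
            f"{spec.total_injected()} defects requested for {spec.n_records} records"
        )
    if spec.duplicate_pairs > spec.n_records:
        raise InfeasibleSpecError("more duplicate pairs than records")
    reserved = {"scientificName", "eventDate", "recordedBy", "geodeticDatum", "country"}
    clash = reserved & set(spec.field_loss_counts)
    if clash:
        raise InfeasibleSpecError(
            f"field-loss injection on {sorted(clash)} would confound the dedicated audits"
        )

    rng = random.Random(spec.seed)
    taxonomy = taxonomy or generate_taxonomy(spec.seed)
    base_kingdom = taxonomy.kingdoms[0]
    pool = taxonomy.by_kingdom(base_kingdom)
    if not pool:
        raise InfeasibleSpecError("taxonomy has no species in its base kingdom")

    chosen = [rng.choice(pool) for _ in range(spec.n_records)]
    pairs = [_base_record(i, chosen[i], rng, dialect) for i in range(spec.n_records)]

    free = list(range(spec.n_records))
    rng.shuffle(free)

    def take() -> int:
        if not free:
            raise InfeasibleSpecError("defect allocation exhausted the record pool")
        return free.pop()

    injector = _NameInjector(taxonomy, rng, dialect)
    for (ctype, detail), count in sorted(spec.name_change_counts.items()):
        for _ in range(count):
            i = take()
            injector.apply(ctype, detail, pairs[i], chosen[i])
            if type_status_for_changes:
                pairs[i].original["typeStatus"] = type_status_for_changes
    for (fclass, outcome), count in sorted(spec.date_outcome_counts.items()):
        for _ in range(count):
            _inject_date(pairs[take()], fclass, outcome)
    for pattern, count in sorted(spec.agent_pattern_counts.items()):
        if pattern == "unchanged":
            continue
        for _ in range(count):
            _inject_agent(pairs[take()], pattern, rng)
    for verdict, count in sorted(spec.datum_verdict_counts.items()):
        if verdict == "correct":
            continue
        for _ in range(count):
            _inject_datum(pairs[take()], verdict)
    for term, count in sorted(spec.field_loss_counts.items()):
        for _ in range(count):
            pair = pairs[take()]
            if not pair.original.get(term, "").strip():
                pair.original[term] = f"supplied {term}"
            pair.processed[term] = ""
    for _ in range(spec.country_mismatches):
        pair = pairs[take()]
        if dialect == "GBIF_DWCA":
            pair.processed["countryCode"] = "MZ"
        else:
            pair.processed["country"] = "Mozambique"

    # Stale duplicates: clones of clean records with an earlier `modified`.
    duplicates = []
    for _ in range(spec.duplicate_pairs):
        i = take()
        clone = RecordPair(
            record_id=pairs[i].record_id + "-old",
            catalog_number=pairs[i].catalog_number,
            original=dict(pairs[i].original),
            processed=dict(pairs[i].processed),
            source=pairs[i].source,
            dataset_tag=pairs[i].dataset_tag,
        )
        clone.original["modified"] = "2016-11-11T10:00:00+12:00"
        clone.processed["modified"] = "2016-11-11T10:00:00+12:00"
        duplicates.append(clone)
    pairs.extend(duplicates)

    realized = SyntheticManifest(
        seed=spec.seed,
        n_records=spec.n_records,
        name_change_counts=dict(spec.name_change_counts),
        date_outcome_counts=dict(spec.date_outcome_counts),
        agent_pattern_counts={
            **{k: v for k, v in spec.agent_pattern_counts.items() if k != "unchanged"},
            "unchanged": spec.n_records
            - sum(v for k, v in spec.agent_pattern_counts.items() if k != "unchanged"),
        },
        datum_verdict_counts={
            **{k: v for k, v in spec.datum_verdict_counts.items() if k != "correct"},
            "correct": spec.n_records
            - sum(v for k, v in spec.datum_verdict_counts.items() if k != "correct"),
        },
        field_loss_counts=dict(spec.field_loss_counts),
        duplicate_pairs=spec.duplicate_pairs,
        country_mismatches=spec.country_mismatches,
    )
    return SyntheticDataset(pairs=pairs, manifest=realized, dialect=dialect)


def example_study_spec(seed: int, n_records: int = 1000, dialect: str = "ALA_TSV") -> SyntheticManifest:
    """A desk-scale defect spec whose mix loosely mirrors an audited museum
    dataset: name changes dominated by up-matches and swap-matches, date
    exclusions dominated by year-only and year-month entries, a tail of
    agent corruption patterns, and scattered datum/loss/country defects.

    The proportions are fixed; only the seed varies between runs.  For the
    GBIF dialect the subgenus-dependent entries are omitted (GBIF strips
    subgenera in processing, so those changes cannot be represented).
    """
    name_changes = {
        ("deleted", "species"): 2,
        ("deleted", "genus"): 1,
        ("fail_match", "species for plant"): 1,
        ("up_match", "species to genus"): 40,
        ("up_match", "species to family"): 15,
        ("up_match", "subspecies to species"): 12,
        ("up_match", "subgenus to genus"): 3,
        ("down_match", "species to subspecies"): 6,
        ("down_match", "genus to subgenus"): 3,
        ("swap_match", "species for species"): 35,
        ("swap_match", "genus for genus"): 4,
        ("subgenus", "added to species"): 8,
        ("subgenus", "deleted from species"): 5,
        ("amended", "species for species"): 15,
        ("amended", "genus for genus"): 2,
    }
    if dialect == "GBIF_DWCA":
        name_changes = {
            (t, d): c
            for (t, d), c in name_changes.items()
            if t != "subgenus" and "subgenus" not in d
        }
    spec = SyntheticManifest(
        seed=seed,
        n_records=n_records,
        name_change_counts=name_changes,
        date_outcome_counts={
            ("YMD", "accepted_full"): 80,
            ("YMD", "excluded"): 30,
            ("Y", "excluded"): 30,
            ("YM", "excluded"): 15,
            ("INTERVAL_DD", "accepted_start_only"): 12,
            ("INTERVAL_DD", "excluded"): 2,
            ("INTERVAL_MD", "accepted_start_only"): 4,
            ("INTERVAL_YMD", "accepted_start_only"): 3,
            ("INTERVAL_Y", "excluded"): 2,
            ("INTERVAL_YM", "excluded"): 2,
            ("DATETIME_TZ", "accepted_full"): 5,
            ("DATETIME_FRAC_TZ", "excluded"): 10,
            ("MALFORMED", "not_applicable"): 3,
        },
        agent_pattern_counts={
            "null_replacement": 8,
            "conjunction_failure": 5,
            "initial_reversal": 4,
            "added_initial": 4,
            "initial_comma": 3,
            "surname_ending_truncation": 3,
            "changed_ok": 10,
        },
        datum_verdict_counts={"incorrect_mapping": 5, "deleted": 4, "unmapped": 2},
        field_loss_counts={"identifiedBy": 30, "locality": 25, "habitat": 10},
        duplicate_pairs=12,
        country_mismatches=5,
    )
    if spec.total_injected() > n_records:
        raise InfeasibleSpecError(f"study spec needs more than {n_records} records")
    return spec


# ---------------------------------------------------------------------------
# Fixture writing (byte-compatible with the dwc_io readers)

_META_XML = """<archive xmlns="http://rs.tdwg.org/dwc/text/">
  <core rowType="http://rs.tdwg.org/dwc/terms/Occurrence" fieldsTerminatedBy="\\t">
    <files><location>occurrence.txt</location></files>
    <id index="0"/>
  </core>
  <extension rowType="http://rs.gbif.org/terms/1.0/VerbatimOccurrence" fieldsTerminatedBy="\\t">
    <files><location>verbatim.txt</location></files>
    <coreid index="0"/>
  </extension>
</archive>
"""


def _ala_columns(quirks: bool) -> list[tuple[str, str, str]]:
    """(header name, side, term) for the ALA fixture, quirks optional."""
    columns: list[tuple[str, str, str]] = [("id", "meta", "id")]
    for term in _BASE_TERMS:
        if term == "basisOfRecord" and quirks:
            columns.append((term, "processed", term))
            columns.append((term, "dup_blank", term))  # duplicated download field
            columns.append((f"{term}_raw", "original", term))
        elif term == "recordedBy" and quirks:
            columns.append((term, "processed", term))
            columns.append((f"{term}_raw", "original", term))
            columns.append((f"{term}_raw", "dup_blank", term))  # 2nd of three
            columns.append((f"{term}_raw", "dup_blank", term))  # 3rd of three
        elif term == "specificEpithet" and quirks:
            columns.append((term, "processed", term))
            columns.append((term, "original", term))  # mislabelled: holds the raw epithet
            columns.append((f"{term}_raw", "dup_blank", term))  # genuinely blank
        else:
            columns.append((term, "processed", term))
            columns.append((f"{term}_raw", "original", term))
    return columns


def write_fixture(dataset: SyntheticDataset, path, dialect: str | None = None,
                  quirks: bool = True) -> None:
    """Write the dataset as files the matching :mod:`dwcaudit.dwc_io` reader
    accepts: a single TSV for ``ALA_TSV`` (with the documented column quirks
    unless ``quirks=False``), or a DwC-A directory (meta.xml, verbatim.txt,
    occurrence.txt) for ``GBIF_DWCA``."""
    dialect = dialect or dataset.dialect
    if dialect == "ALA_TSV":
        columns = _ala_columns(quirks)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(name for name, _, _ in columns) + "\n")
            for pair in dataset.pairs:
                row = []
                for _, side, term in columns:
                    if side == "meta":
                        row.append(pair.record_id)
                    elif side == "original":
                        row.append(pair.original.get(term, ""))
                    elif side == "processed":
                        row.append(pair.processed.get(term, ""))
                    else:
                        row.append("")
                fh.write("\t".join(row) + "\n")
        return
    if dialect == "GBIF_DWCA":
        os.makedirs(path, exist_ok=True)
        orig_terms = sorted({t for p in dataset.pairs for t in p.original})
        proc_terms = sorted({t for p in dataset.pairs for t in p.processed})
        with open(os.path.join(path, "meta.xml"), "w", encoding="utf-8") as fh:
            fh.write(_META_XML)
        with open(os.path.join(path, "verbatim.txt"), "w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(["id"] + orig_terms) + "\n")
            for pair in dataset.pairs:
                fh.write(
                    "\t".join([pair.record_id] + [pair.original.get(t, "") for t in orig_terms])
                    + "\n"
                )
        with open(os.path.join(path, "occurrence.txt"), "w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(["id"] + proc_terms) + "\n")
            for pair in dataset.pairs:
                fh.write(
                    "\t".join([pair.record_id] + [pair.processed.get(t, "") for t in proc_terms])
                    + "\n"
                )
        return
    raise InfeasibleSpecError(f"unknown dialect {dialect!r}")
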