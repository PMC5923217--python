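# dwcaudit

**Audit aggregator processing effects on Darwin Core occurrence records.**

Biodiversity aggregators such as the Atlas of Living Australia (ALA) and the
Global Biodiversity Information Facility (GBIF) do not simply republish the
occurrence records that museums and herbaria provide: they *process* them —
matching supplied taxon names against reference classifications, parsing
dates and collector strings, mapping geodetic datums to EPSG codes, and
assigning countries from coordinates. Processing can silently replace a
formal scientific name with a different one, blank out supplied field values,
reject well-formed dates, or attach a holotype to a name it was never the
type of. `dwcaudit` is a toolkit for *measuring* these effects: it aligns
the original ("verbatim"/raw) and processed versions of each record,
classifies every taxon-name transition, and quantifies non-taxonomic defects
field by field.

It is aimed at collection data managers, biodiversity informaticians and
end-users of aggregated occurrence data who want to know, dataset-wide, what
processing changed.

## The name-change typology

For each record with a formal genus- or species-group name, the transition
from original `scientificName` to processed `scientificName` is classified
into exactly one of seven categories:

| type | meaning |
|---|---|
| `deleted` | processed name is blank — the name was filtered out |
| `fail-match` | replaced with *incertae sedis* or a name from an unrelated branch (kingdom/phylum conflict), or a listed known bad match |
| `up-match` | generalised to a higher rank (e.g. *Oliva parkinsoni* → *Oliva*) |
| `down-match` | particularised to a lower rank (e.g. *Arrenurus (Arrenurus)* → *Arrenurus madaraszi*) |
| `swap-match` | replaced at the same rank (for ALA, includes species differing only in subgenus) |
| `subgenus` | subgenus added or deleted, nothing else major (ALA only — GBIF strips subgenera) |
| `amended` | minor spelling/format change (per-token edit distance ≤ 2, same initial) |

A single processed name can embody several changes at once; each record is
counted once at the highest-precedence type, with precedence
`fail-match > (up-match = down-match) > swap-match > subgenus > amended`.
Authorship differences and changes confined to the higher classification
never count as name changes.

Around the classifier sit audits for field-level data loss (non-blank
original, blank processed), date processing (a twelve-class format grammar
covering ISO interval shorthands like `1943-06-20/21` and timezone
datetimes), collector-string corruption (null replacement, conjunction
failure, initial reversal/addition, leading commas, `...and` surname
truncation), geodetic-datum mapping (WGS84 → EPSG:4326, AGD66 → EPSG:6202,
...), verbatim elevation conversion (feet × 0.3048), GBIF's min/max →
centre/accuracy depth collapse, and country assignment.

Because real aggregator downloads are hundreds of megabytes, the package
includes a synthetic generator that emulates paired original/processed
tables in both dialects (ALA-style TSV with its documented duplicated and
mislabeled columns; GBIF-style Darwin Core archives) with a configurable
count of every defect class and a ground-truth manifest — every pipeline
stage is testable at desk scale.

## Worked example

Generate a 1,000-record synthetic study and audit it:

```sh
dwcaudit simulate --spec examples/study.yaml --seed 1 --out scratch/sim
dwcaudit names  --ala scratch/sim/ala_fixture.tsv --out scratch/names
dwcaudit dates  --ala scratch/sim/ala_fixture.tsv --out scratch/dates
```

`scratch/names/tally.tsv` then holds rows such as

```
changeType	changeDetail	count
up-match	species to genus	40
swap-match	species for species	35
amended	species for species	15
subgenus	added to species	8
```

meaning, e.g., that 40 records had their species name generalised to the
bare genus, and `scratch/names/changes.pipe` holds the per-record change
table in the audit's six-column layout:

```
C.100008 | Perine guroze Pove, 1951 | Perine | up-match | species to genus |
```

The same commands accept real ALA TSV downloads (`--ala`) and GBIF Darwin
Core archives (`--gbif`); `dwcaudit fields/agents/geo` cover the loss,
collector-string and datum/country audits, and `dwcaudit compare` tabulates
cross-aggregator agreement from two change tables.

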