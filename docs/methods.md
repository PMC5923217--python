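# Methods

This note documents the models and procedures behind `dwcaudit`, the
parameters that matter, the design decisions taken where the methodology was
genuinely open, and what the synthetic benchmark does and does not show.

## Record pairing

Both supported dialects carry each record twice: as supplied by the provider
and as processed by the aggregator.

* **ALA TSV**: `_raw`-suffixed columns are the original values. Real
  downloads contain structural quirks the reader resolves positionally:
  duplicated columns (two `basisOfRecord`, three `recordedBy_raw`) collapse
  to the first non-blank value, and the *second* `specificEpithet` column —
  which, contrary to its header, holds the originally supplied epithet — is
  remapped to the original side while the nominal `specificEpithet_raw`
  column (blank in practice) is ignored unless it has content. First-non-blank
  collapse is a deliberate tie-break: it is deterministic, order-stable, and
  correct for the simple-duplicate case where the replicates are either equal
  or blank.
* **GBIF DwC-A**: `verbatim.txt` is the original table, `occurrence.txt` the
  processed one, joined on the core id; `meta.xml` is honoured for file
  locations when present, else the header rows name the columns. Columns
  present in only one table stay on that side, so "column absent" (e.g.
  `scientificNameAuthorship`, dropped in processing) is distinguishable from
  "present but blank". Ids found in exactly one table are excluded from
  pairing and reported as warnings.

Files are decoded as UTF-8 with replacement; TSV cells are taken verbatim
(no quote interpretation) because aggregator TSVs are bare, not RFC-4180.

Cross-aggregator alignment joins on whitespace-trimmed `catalogNumber`.
Keys duplicated *within* one dataset are excluded from the matched set and
counted separately: with an ambiguous join there is no defensible record
pairing, and counting keeps the partition `matched + only + duplicates =
total` exact. Stale duplicates (same `catalogNumber`, differing `modified`)
are reduced to the latest parseable version; a group with an unparseable
timestamp is kept intact and flagged rather than guessed at.

## Name parsing

The parser handles the grammar occurring in museum occurrence data:
uninomials, `Genus (Subgenus)`, binomials, trinomials, with authorship that
is bare (`Lea`), comma-year (`Fruhstorfer, 1911`) or parenthesised
(`(Iredale, 1943)`). Two disambiguation rules do the real work:

* a parenthesised group directly after the genus that is a single
  capitalised word with **no comma-year** is a subgenus; any group containing
  a comma-year is authorship — this separates `(Costellaria)` from
  `(Iredale, 1943)`;
* authorship otherwise starts at the first capitalised token after the
  lowest epithet.

Rank is inferred from structure (epithets present ⇒ species/subspecies,
subgenus only ⇒ subgenus). For uninomials the record's own context decides:
a match against the `genus` field ⇒ genus; a match against a
higher-classification field ⇒ that rank; a declared `taxonRank` consistent
with the structure is honoured; otherwise the name is an above-genus
uninomial of unknown level and is excluded from rank-dependent
classification as an error finding. Names are compared case-insensitively
with diacritics folded, since capitalisation and encoding vary by provider.

A name is **informal** — and its record excluded from the name audit — when
the name proper (authorship excluded, so years do not trigger) matches a
configurable marker set: `n.sp.`, `sp.`, `spp.`, `aff.`, `cf.`, `indet.`,
digits, underscores, question marks. The audited datasets' conventions
motivate the defaults (`Idiosepius _n.sp._2` is the canonical informal
example); the set is a documented choice, not a nomenclatural standard.

## Change classification

The decision procedure applies the typology in strict precedence order
(deleted first, then fail-match > up/down-match > swap-match > subgenus >
amended), so every pair maps to exactly one type and composite changes (an
up-match that is also a swap at the higher rank) are counted once at the
higher precedence:

1. blank processed name ⇒ `deleted`;
2. `fail_match` when the processed canonical is *incertae sedis*, when the
   two sides disagree at kingdom or phylum, or when the pair appears in a
   user-supplied overrides list. Automatic detection is deliberately limited
   to these signals: a same-rank replacement by a non-synonym (*Nuculana
   pala* → *N. pella*) is indistinguishable from a legitimate synonym swap
   without a synonymy reference, which is exactly why the overrides list
   exists;
3. differing resolvable ranks ⇒ `up_match`/`down_match` on a fixed ladder
   (kingdom … order, superfamily, family, subfamily, tribe, genus, subgenus,
   species, subspecies — the intercalated family-group ranks sit between
   order and genus, as the change-detail vocabulary requires);
4. same rank with a token replaced outright ⇒ `swap_match`; for ALA
   records, species-group names whose subgenera differ are also swaps;
5. subgenus presence differing with everything else minor ⇒ `subgenus`
   (ALA only; the rule is source-conditional because GBIF strips subgenera
   during processing, so for GBIF records subgenus presence is canonicalised
   away before comparison and such pairs classify as `none`);
6. all tokens within the amendment threshold ⇒ `amended`;
7. otherwise `none`. Authorship never participates.

**`amended_threshold`** (default 2, per token, same initial letter required)
quantifies "minor spelling change". The in-corpus amended examples
(*discolor* → *discolora*, *antonelli* → *antonellii*) are within distance 2
with the initial preserved, and requiring the same initial keeps short
epithets from amending into unrelated words. Edit distances come from
`edlib` (Needleman–Wunsch); the test suite cross-checks it against an
independent dynamic-programming oracle.

Fail-match details are rendered `"<rank> for plant"`-style when a kingdom
conflict triggered the call (the kingdom rendered informally:
Plantae → plant), and `"<rank> for/to <rank>"` otherwise.

## Value audits

**Dates.** The audit defines a normative twelve-class grammar: `Y`, `YM`,
`YMD`, `YMD_loose` (single-digit month/day), five interval shorthands
(`…/DD` borrows year and month from the start, `…/MM-DD` borrows the year,
plus full, year-only and year-month ends), two timezone datetime classes
(with and without fractional seconds), and `MALFORMED` for everything else —
including an interval whose expanded start exceeds its end
(`2006-09-02/2005-11-20`). Year-only and year-month interval *ends* expand
to the last day of the stated year/month so the start ≤ end check is
well-defined. "Valid" means any class but `MALFORMED`. Processing outcomes:
`excluded` (valid raw, blank processed), `accepted_start_only` (processed
equals the interval start), `accepted_full` (content preserved, allowing
zero-padding normalisation), `altered`, `not_applicable`. Timezone content
is preserved but not validated; only class membership matters.

**Agent strings.** Processed multi-agent values use `|` as separator. Seven
independent detectors target the systematic corruption patterns seen in
aggregator output: `null` elements; leading commas; `…and`-final surnames
cut at the false conjunction; first-name/middle-initial reversal; spurious
added initials; conjunction failure (two processed elements sharing a
surname the raw string assigns to at most one agent — raw initial-only
segments such as `J.` legitimately share the following surname, so
`J.& D.Freeman → Freeman, J.|Freeman, D.` does *not* fire — or a processed
surname not derivable from any raw token). Surname extraction is a
documented heuristic: text before the first comma in `Surname, Rest` forms,
else the final alphabetic token longer than one letter. `unchanged` is
exclusive; a changed pair firing no detector is `changed_ok`.

**Geodetic datum.** Verdicts against an editable label → EPSG table
(defaults: WGS84 → EPSG:4326, AGD66 → EPSG:6202, AGD84 → EPSG:6203,
GDA94 → EPSG:4283; labels compared case-insensitively, spaces removed):
`correct`, `incorrect_mapping` (a known-form code other than the mapped
one), `deleted`, `unmapped`.

**Elevation/depth.** Verbatim elevations convert with exactly 0.3048 m/ft;
plain numbers are metres; ranges convert endpoint-wise; anything else is
unparseable. GBIF's recomputed depth fields are checked against
centre = (min+max)/2, accuracy = (max−min)/2 (the mean absolute deviation of
the two endpoints); min > max is an invalid-range finding.

**Field loss.** For a term, `lost` = non-blank original with blank (or
absent) processed; `never_supplied` = blank original; blank means empty or
whitespace-only. The literal string `null` counts as content here — it is a
*corruption*, detected by the agent audit, not an absence.

**Country.** Provider country vs processed country/`countryCode` via a small
name ↔ ISO-3166 table; `not_assessable` when either side is blank. No
point-in-polygon georeferencing is attempted: wrong-country assignments are
detected from field disagreement only.

## Synthetic data: what it emulates, and what it does not

The generator builds records over a toy ranked taxonomy
(kingdom → species, configurable fan-out, consonant-vowel names that are
parseable by construction and free of informal markers; the first kingdom is
Animalia and all base records come from it, the second is Plantae and donates
cross-kingdom fail-matches). Each requested defect is constructed as the
*inverse* of the corresponding audit definition — up-match "species to
genus" truncates to the genus, amended edits one character preserving the
initial, a swap substitutes an epithet with a different initial, subgenus
defects insert/remove a parenthesised subgenus (ALA dialect only), date and
agent defects instantiate each format/pattern — and lands on its own record,
so tallies partition cleanly. Stale-duplicate rows are appended clones of
clean records with an earlier `modified`. The realized manifest also fills
in baseline counts the audits will see (`unchanged` agents, `correct`
datums) so dataset summaries equal it exactly. A single seeded
`random.Random` stream with fixed draw order makes fixtures byte-identical
per (seed, spec).

The standard study spec (`example_study_spec`) fixes a defect mix loosely
mirroring an audited museum dataset at 1,000 records: ~15% of records with
name changes dominated by up-matches and swap-matches, date exclusions
dominated by year-only/year-month entries, a tail of collector-string
patterns, and scattered datum/loss/country defects. Only the seed varies.

What passing the recovery benchmark shows: the pipeline is *internally
consistent* — every defect the definitions describe is detected, exactly
once, at any seed, through a full write/read/audit round trip in both
dialects. What it does not show: performance on real data, where informal
names are messier than the marker set, collector strings are more varied
than the seven patterns, name frequencies are highly skewed, and defects
co-occur on single records. Field-loss injection is restricted to terms not
covered by a dedicated audit (requesting loss on `recordedBy`, say, would
confound the agent tally and is rejected as infeasible).

## Problem sizes and runtime

The default test suite and the acceptance script use 300–1,000-record
synthetic datasets, a 20-seed recovery sweep, 10,000 random string pairs for
the edit-distance cross-check, and a few hundred property-test examples per
invariant — sizes chosen so a complete run takes seconds while every code
path (both dialects, every defect family, all precedence interactions) is
exercised. Auditing real aggregator downloads (10⁵–10⁶ records) is
supported through the same CLI and is CPU-bound in name parsing; expect
minutes, not seconds.

## Known limitations

* No name resolution against reference taxonomies (National Species Lists,
  GBIF backbone), no synonymy lookup, no homonym detection: fail-matches
  beyond the incertae-sedis/kingdom-conflict signals require the overrides
  list.
* Agent surname heuristics will misread cultural name orders and compound
  surnames; detectors are tuned to the corruption patterns of one processing
  pipeline.
* The date grammar is normative, not exhaustive of ISO 8601 (no week dates,
  no ordinal dates); unlisted formats classify as `MALFORMED`.
* Uninomial rank inference depends on the record's higher-classification
  fields; records with bare uninomials and empty higher taxa are excluded as
  classification errors rather than guessed.
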