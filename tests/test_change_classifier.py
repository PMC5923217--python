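"""Name-change typology: classification, precedence, tallies, agreement."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwcaudit.change_classifier import (
    ClassificationError,
    NameChange,
    classify_change,
    compare_aggregators,
    tabulate_changes,
    type_status_crosstab,
)
from dwcaudit.names import parse_scientific_name

CASES = [
    # (original, proc, orig_higher, proc_higher, proc_kwargs, source, type, detail)
    ("Jaffaia jaffaensis (Blochmann, 1910)", "", None, None, {}, "ALA",
     "deleted", "species"),
    ("Lasiocephala basalis", "Drosera sect. Lasiocephala",
     {"kingdom": "Animalia"}, {"kingdom": "Plantae"}, {}, "ALA",
     "fail_match", "species for plant"),
    ("Oliva parkinsoni Prior, 1975", "Oliva", None, None,
     {"higher_genus": "Oliva"}, "ALA", "up_match", "species to genus"),
    ("Arrenurus (Arrenurus)", "Arrenurus madaraszi", None, None, {}, "ALA",
     "down_match", "subgenus to species"),
    ("Polyphrades brevirostris Lea", "Essolithna rhombus", None, None, {}, "ALA",
     "swap_match", "species for species"),
    ("Vexillum (Costellaria) antonelli (Dohrn, 1861)", "Vexillum antonellii",
     None, None, {}, "ALA", "subgenus", "deleted from species"),
    ("Hasora discolor mastusia Fruhstorfer, 1911", "Hasora discolora mastusia",
     None, None, {}, "ALA", "amended", "subspecies for subspecies"),
    ("Culex (Lutzia) douglasi Dobrotworsky", "Culex (Neoculex) douglasi",
     None, None, {}, "ALA", "swap_match", "species for species"),
    ("Erronea chrysostoma Schilder, 1927", "Erronea", None, None,
     {"higher_genus": "Erronea"}, "GBIF", "up_match", "species to genus"),
    # identical names: no change; authorship differences never count
    ("Oliva parkinsoni Prior, 1975", "Oliva parkinsoni", None, None, {}, "ALA",
     "none", ""),
    # incertae sedis replacement
    ("Oliva parkinsoni", "incertae sedis", None, None, {}, "GBIF",
     "fail_match", "species for incertae sedis"),
    # subgenus-presence-only change is invisible to GBIF
    ("Vexillum (Costellaria) antonelli", "Vexillum antonelli", None, None, {},
     "GBIF", "none", ""),
    # subgenus-rank names swapped at the genus position
    ("Lipotriches (Hoplonomia)", "Nomia (Hoplonomia)", None, None, {}, "ALA",
     "swap_match", "subgenus for subgenus"),
    ("Erronea chrysostoma", "Erronea ovum chrysostoma", None, None, {}, "ALA",
     "down_match", "species to subspecies"),
]


@pytest.mark.parametrize("orig,proc,oh,ph,pk,src,ctype,detail", CASES)
def test_classification_typology(orig, proc, oh, ph, pk, src, ctype, detail):
    original = parse_scientific_name(orig)
    processed = parse_scientific_name(proc, **pk) if proc else None
    change = classify_change(
        original, processed, orig_higher=oh, proc_higher=ph, source=src,
        catalog_number="X1",
    )
    assert (change.change_type, change.change_detail) == (ctype, detail)


def test_rank_change_outranks_token_swap():
    """An up-match that is also a swap at the higher level counts as
    up-match only (records are counted once, at the higher precedence)."""
    original = parse_scientific_name("Anaxo cylindricus obscurus Blackburn")
    processed = parse_scientific_name("Lepturidea cylindrica")
    change = classify_change(original, processed, source="ALA")
    assert change.change_type == "up_match"
    assert change.change_detail == "subspecies to species"


def test_overrides_force_fail_match():
    original = parse_scientific_name("Nuculana pala (Hedley, 1907)")
    processed = parse_scientific_name("Nuculana pella (Linnaeus, 1758)")
    plain = classify_change(original, processed, source="GBIF")
    assert plain.change_type == "amended"  # one-letter change, undetectable
    overridden = classify_change(
        original, processed, source="GBIF",
        overrides={("nuculana pala", "nuculana pella")},
    )
    assert overridden.change_type == "fail_match"
    assert overridden.change_detail == "species for species"


def test_unresolvable_rank_raises():
    original = parse_scientific_name("Oliva parkinsoni")
    stray = parse_scientific_name("Wandering uninomialis-oddity 77")
    with pytest.raises(ClassificationError):
        classify_change(original, stray, source="ALA")


def _mk(cat, ctype, detail="", status="", source="ALA"):
    return NameChange(
        catalog_number=cat, original_name="A b", processed_name="C d",
        change_type=ctype, change_detail=detail, type_status=status, source=source,
    )


def test_tabulate_counts_records_and_excludes_none():
    changes = [
        _mk("1", "up_match", "species to genus"),
        _mk("2", "up_match", "species to genus"),
        _mk("3", "deleted", "genus"),
        _mk("4", "none"),
    ]
    tally = tabulate_changes(changes, total_examined=10)
    assert tally.rows[("up_match", "species to genus")] == 2
    assert tally.rows[("deleted", "genus")] == 1
    assert tally.total_changed == 3
    assert sum(tally.rows.values()) == tally.total_changed <= tally.total_examined


def test_compare_aggregators_partition_and_matrix():
    ala = [_mk("1", "swap_match"), _mk("2", "up_match"), _mk("3", "amended")]
    gbif = [_mk("2", "up_match", source="GBIF"), _mk("3", "up_match", source="GBIF"),
            _mk("4", "swap_match", source="GBIF")]
    report = compare_aggregators(ala, gbif, matched_keys={"1", "2", "3", "4"})
    assert (report.only_a, report.both, report.only_b) == (1, 2, 1)
    assert report.type_matrix[("up_match", "up_match")] == 1
    assert report.type_matrix[("amended", "up_match")] == 1
    assert sum(report.type_matrix.values()) == report.both


def test_compare_aggregators_disjoint_sets():
    report = compare_aggregators([_mk("1", "up_match")], [_mk("2", "up_match")],
                                 matched_keys={"1", "2"})
    assert (report.only_a, report.both, report.only_b) == (1, 0, 1)
    assert not report.type_matrix


def test_type_status_crosstab_matches_substring():
    changes = [
        _mk("1", "swap_match", status="Holotype"),
        _mk("2", "up_match", status="holotype of Aus bus"),
        _mk("3", "up_match", status="Paratype"),
        _mk("4", "none", status="Holotype"),
        _mk("5", "up_match", status="SYNTYPE"),
    ]
    counts = type_status_crosstab(changes)
    assert counts == {"swap_match": 1, "up_match": 2}
    assert type_status_crosstab([]) == {}


_EPITHETS = st.from_regex(r"[bdglmnprst][aeiou][bdglmnprst][aeiou][bdglmnprst][aeiou]",
                          fullmatch=True)
_GENERA = _EPITHETS.map(str.capitalize)


@st.composite
def name_pairs(draw):
    """Arbitrary formal original and processed name strings."""

    def one(genus):
        sub = draw(st.one_of(st.just(""), _GENERA))
        n = draw(st.integers(0, 2))
        eps = [draw(_EPITHETS) for _ in range(n)]
        parts = [genus] + ([f"({sub})"] if sub else []) + eps
        return " ".join(parts)

    g1 = draw(_GENERA)
    g2 = draw(st.one_of(st.just(g1), _GENERA))
    return one(g1), one(g2)


@settings(derandomize=True, max_examples=400)
@given(name_pairs(), st.sampled_from(["ALA", "GBIF"]))
def test_every_pair_gets_exactly_one_type(pair, source):
    orig_s, proc_s = pair
    original = parse_scientific_name(orig_s, higher_genus=orig_s.split()[0])
    processed = parse_scientific_name(proc_s, higher_genus=proc_s.split()[0])
    change = classify_change(original, processed, source=source)
    assert change.change_type in (
        "none", "deleted", "fail_match", "up_match", "down_match",
        "swap_match", "subgenus", "amended",
    )
    again = classify_change(original, processed, source=source)
    assert (again.change_type, again.change_detail) == (
        change.change_type, change.change_detail)


@settings(derandomize=True, max_examples=400)
@given(name_pairs(), st.sampled_from(["Author", "Author, 1901", "(Author, 1901)"]))
def test_authorship_is_invisible_to_classification(pair, author):
    orig_s, proc_s = pair
    bare_o = parse_scientific_name(orig_s, higher_genus=orig_s.split()[0])
    bare_p = parse_scientific_name(proc_s, higher_genus=proc_s.split()[0])
    # authorship only attaches below genus rank in the grammar
    deco_o = parse_scientific_name(
        orig_s + (" " + author if " " in orig_s and "(" not in orig_s.split()[1] else ""),
        higher_genus=orig_s.split()[0],
    )
    deco_p = parse_scientific_name(proc_s, higher_genus=proc_s.split()[0])
    plain = classify_change(bare_o, bare_p, source="ALA")
    decorated = classify_change(deco_o, deco_p, source="ALA")
    assert (plain.change_type, plain.change_detail) == (
        decorated.change_type, decorated.change_detail)
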