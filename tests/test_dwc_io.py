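"""Readers (ALA TSV quirks, DwC-A), alignment, dedupe, change tables."""

import os

import pytest

from dwcaudit.change_classifier import NameChange
from dwcaudit.dwc_io import (
    DialectError,
    RecordPair,
    align_pairs,
    dedupe_by_modified,
    read_ala_table,
    read_change_table,
    read_gbif_dwca,
    write_change_table,
)


def _write(path, text):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(text)


def test_ala_reader_resolves_duplicate_and_mislabeled_columns(tmp_path):
    # two basisOfRecord, three recordedBy_raw, two specificEpithet plus a
    # blank specificEpithet_raw: the documented download quirks
    header = "\t".join([
        "id", "catalogNumber_raw", "catalogNumber",
        "basisOfRecord", "basisOfRecord",
        "recordedBy", "recordedBy_raw", "recordedBy_raw", "recordedBy_raw",
        "specificEpithet", "specificEpithet", "specificEpithet_raw",
        "scientificName_raw", "scientificName",
    ])
    row = "\t".join([
        "u1", "C.1", "C.1",
        "PreservedSpecimen", "",
        "Smith, A.", "A.Smith", "", "",
        "parkinsoni", "parkinsonii", "",
        "Oliva parkinsonii", "Oliva parkinsoni",
    ])
    path = tmp_path / "ala.tsv"
    _write(path, header + "\n" + row + "\n")
    pairs = read_ala_table(path)
    assert len(pairs) == 1
    rec = pairs[0]
    assert rec.record_id == "u1"
    assert rec.catalog_number == "C.1"
    assert rec.processed["basisOfRecord"] == "PreservedSpecimen"
    assert rec.original["recordedBy"] == "A.Smith"
    # first specificEpithet column is the processed value, the second holds
    # the originally supplied epithet
    assert rec.processed["specificEpithet"] == "parkinsoni"
    assert rec.original["specificEpithet"] == "parkinsonii"
    assert rec.original["scientificName"] == "Oliva parkinsonii"


def test_ala_reader_header_only_and_row_errors(tmp_path):
    path = tmp_path / "empty.tsv"
    _write(path, "id\tscientificName\tscientificName_raw\n")
    assert list(read_ala_table(path)) == []

    path2 = tmp_path / "ragged.tsv"
    _write(path2, "id\ta\ta_raw\n1\tx\ty\n2\tonly-two\n3\tp\tq\n")
    result = read_ala_table(path2)
    assert len(result) == 2
    assert len(result.row_errors) == 1
    assert result.row_errors[0][0] == 3  # 1-based file line number

    blank = tmp_path / "blank.tsv"
    _write(blank, "")
    with pytest.raises(DialectError):
        read_ala_table(blank)


def test_dwca_reader_pairs_and_one_sided_columns(tmp_path):
    dwca = tmp_path / "dwca"
    os.makedirs(dwca)
    _write(dwca / "verbatim.txt",
           "id\tcatalogNumber\tscientificName\tscientificNameAuthorship\n"
           "1\tC.1\tOliva parkinsoni\tPrior, 1975\n"
           "2\tC.2\tOliva oliva\tLinnaeus\n"
           "3\tC.3\tOliva x\t\n")
    _write(dwca / "occurrence.txt",
           "id\tcatalogNumber\tscientificName\n"
           "1\tC.1\tOliva parkinsoni\n"
           "2\tC.2\tOliva oliva\n"
           "9\tC.9\tGhost record\n")
    result = read_gbif_dwca(dwca)
    assert len(result) == 2
    assert len(result.warnings) == 2  # verbatim id 3 and occurrence id 9
    rec = result[0]
    assert rec.source == "GBIF"
    # authorship column dropped in processing: present only on the original side
    assert "scientificNameAuthorship" in rec.original
    assert "scientificNameAuthorship" not in rec.processed
    assert rec.original["scientificName"] == rec.processed["scientificName"]


def _pair(cat, modified="", **extra):
    original = {"catalogNumber": cat, "modified": modified, **extra}
    return RecordPair(cat, cat, original, dict(original))


def test_align_pairs_counts_and_symmetry():
    a = [_pair(f"S{i}") for i in range(10)] + [_pair(f"A{i}") for i in range(3)]
    b = [_pair(f"S{i}") for i in range(10)] + [_pair(f"B{i}") for i in range(2)]
    fwd = align_pairs(a, b)
    assert (len(fwd.matched), fwd.only_a, fwd.only_b) == (10, 3, 2)
    rev = align_pairs(b, a)
    assert (len(rev.matched), rev.only_a, rev.only_b) == (10, 2, 3)
    assert align_pairs([], []) == ([], 0, 0, 0, 0)


def test_align_pairs_excludes_within_dataset_key_collisions():
    a = [_pair("S1"), _pair("S1"), _pair("S2")]
    b = [_pair("S1"), _pair("S2")]
    result = align_pairs(a, b)
    assert len(result.matched) == 1  # only S2; S1 is ambiguous within a
    assert result.dup_a == 2 and result.dup_b == 0
    assert len(result.matched) + result.only_a + result.dup_a == len(a)


def test_dedupe_keeps_latest_parseable_version():
    records = [
        _pair("C.1", "2016-11-11"),
        _pair("C.1", "2017-05-09"),
        _pair("C.2", "2017-05-09"),
    ]
    result = dedupe_by_modified(records)
    assert len(result) == 2
    assert result.removed == 1
    kept = [r for r in result if r.catalog_number == "C.1"][0]
    assert kept.original["modified"] == "2017-05-09"

    untouched = dedupe_by_modified([_pair("C.3", "2017-05-09")])
    assert len(untouched) == 1 and untouched.removed == 0

    # unparseable timestamp in a duplicate group: keep the group, flag it
    flagged = dedupe_by_modified([_pair("C.4", "yesterday"), _pair("C.4", "2017-05-09")])
    assert len(flagged) == 2
    assert flagged.flagged_groups == ["C.4"]


CULEX = NameChange(
    catalog_number="T4607",
    original_name="Culex (Lutzia) douglasi Dobrotworsky",
    processed_name="Culex (Neoculex) douglasi",
    change_type="swap_match",
    change_detail="species for species",
    type_status="Holotype",
    source="ALA",
)


def test_change_table_pipe_layout_matches_audit_convention(tmp_path):
    path = tmp_path / "changes.pipe"
    write_change_table([CULEX], path, "PIPE")
    line = path.read_text(encoding="utf-8").rstrip("\n")
    assert line == (
        "T4607 | Culex (Lutzia) douglasi Dobrotworsky | Culex (Neoculex) douglasi"
        " | swap-match | species for species | Holotype"
    )


@pytest.mark.parametrize("fmt", ["PIPE", "TSV"])
def test_change_table_round_trip(tmp_path, fmt):
    changes = [CULEX] + [
        NameChange(f"C.{i}", f"Aus bus{i}", f"Aus cus{i}", "swap_match",
                   "species for species", "", "ALA")
        for i in range(50)
    ]
    path = tmp_path / f"changes.{fmt.lower()}"
    write_change_table(changes, path, fmt)
    assert read_change_table(path, fmt, source="ALA") == changes

    empty = tmp_path / f"empty.{fmt.lower()}"
    write_change_table([], empty, fmt)
    assert read_change_table(empty, fmt) == []
    text = empty.read_text(encoding="utf-8")
    assert text.startswith("catalogNumber") if fmt == "TSV" else text == ""
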