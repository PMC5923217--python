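"""Date, agent, datum, elevation, depth, country and field-loss audits."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwcaudit.dwc_io import RecordPair
from dwcaudit.value_audits import (
    audit_agent,
    audit_country,
    audit_date_processing,
    audit_datum,
    classify_date,
    convert_verbatim_elevation,
    depth_summary,
    field_loss,
)


@pytest.mark.parametrize(
    "raw,cls,start,end",
    [
        ("1943-06-20/21", "INTERVAL_DD", date(1943, 6, 20), date(1943, 6, 21)),
        ("1943-06-20/07-02", "INTERVAL_MD", date(1943, 6, 20), date(1943, 7, 2)),
        ("1943-06-20/1943-06-25", "INTERVAL_YMD", date(1943, 6, 20), date(1943, 6, 25)),
        ("1943-06-20/1944", "INTERVAL_Y", date(1943, 6, 20), date(1944, 12, 31)),
        ("1943-06-20/1943-08", "INTERVAL_YM", date(1943, 6, 20), date(1943, 8, 31)),
        ("2006-09-02/2005-11-20", "MALFORMED", None, None),
        ("1985-10-06", "YMD", date(1985, 10, 6), None),
        ("1985-1-6", "YMD_loose", date(1985, 1, 6), None),
        ("1987", "Y", None, None),
        ("1987-06", "YM", None, None),
        ("1987-13", "MALFORMED", None, None),
        ("2017-05-09T10:00:00+12:00", "DATETIME_TZ", date(2017, 5, 9), None),
        ("2017-05-09T10:00:00.000+12:00", "DATETIME_FRAC_TZ", date(2017, 5, 9), None),
        ("2016-11-11T10:00:00Z", "DATETIME_TZ", date(2016, 11, 11), None),
        ("", "MALFORMED", None, None),
        ("12 June 1987", "MALFORMED", None, None),
        ("1999-02-30", "MALFORMED", None, None),
    ],
)
def test_date_format_grammar(raw, cls, start, end):
    audit = classify_date(raw)
    assert audit.format_class == cls
    assert audit.interval_start == start
    if end is not None:
        assert audit.interval_end == end


@pytest.mark.parametrize(
    "raw,processed,outcome",
    [
        ("1943-06-20/21", "1943-06-20", "accepted_start_only"),
        ("1985-10-06", "", "excluded"),
        ("2000-01-01", "2000-01-01", "accepted_full"),
        ("1999-1-2", "1999-01-02", "accepted_full"),
        ("1985-10-06", "1985-10-07", "altered"),
        ("", "", "not_applicable"),
        ("garbage", "", "not_applicable"),
    ],
)
def test_date_processing_outcomes(raw, processed, outcome):
    assert audit_date_processing(raw, processed).outcome == outcome


@settings(derandomize=True, max_examples=200)
@given(
    st.dates(min_value=date(1800, 1, 1), max_value=date(2030, 12, 31)),
    st.integers(0, 40),
)
def test_interval_expansion_is_ordered_and_start_reclassifies(start, span):
    # full-interval form with an end `span` days after the start
    end = date.fromordinal(start.toordinal() + span)
    audit = classify_date(f"{start.isoformat()}/{end.isoformat()}")
    assert audit.format_class == "INTERVAL_YMD"
    assert audit.interval_start <= audit.interval_end
    assert classify_date(audit.interval_start.isoformat()).format_class == "YMD"
    # reversed endpoints are malformed unless the interval is a single day
    reversed_audit = classify_date(f"{end.isoformat()}/{start.isoformat()}")
    if span:
        assert reversed_audit.format_class == "MALFORMED"


AGENT_CASES = [
    ("A.Musgrave & E.LeG.Troughton", "Musgrave, A.|null", {"null_replacement"}),
    ("J.Brazier & G.Rossiter", "Rossiter, J.|Rossiter, G.", {"conjunction_failure"}),
    ("Harvey, Michael S.", "Harvey, S. Michael", {"initial_reversal"}),
    ("Houghton, Noel", "Houghton, N. Noel", {"added_initial"}),
    ("B.M.R.", ", B.M.R.", {"initial_comma"}),
    ("M. Crossland", ", M. Crossl|", {"surname_ending_truncation", "initial_comma"}),
    ("J.& D.Freeman", "Freeman, J.|Freeman, D.", {"changed_ok"}),
    ("Abbott, E.", "Abbott, E.", {"unchanged"}),
]


@pytest.mark.parametrize("raw,processed,patterns", AGENT_CASES)
def test_agent_patterns(raw, processed, patterns):
    assert set(audit_agent(raw, processed).patterns) == patterns


def test_agent_unchanged_is_exclusive():
    for raw, processed, _ in AGENT_CASES:
        audit = audit_agent(raw, raw)
        assert set(audit.patterns) == {"unchanged"}


@pytest.mark.parametrize(
    "raw,processed,verdict",
    [
        ("WGS84", "EPSG:4326", "correct"),
        ("WGS 84", "EPSG:4326", "correct"),
        ("AGD66", "EPSG:4326", "incorrect_mapping"),
        ("AGD66", "EPSG:6202", "correct"),
        ("WGS84", "", "deleted"),
        ("LOCALGRID1", "EPSG:4326", "unmapped"),
    ],
)
def test_datum_mapping(raw, processed, verdict):
    assert audit_datum(raw, processed).datum_verdict == verdict


def test_elevation_conversion():
    assert convert_verbatim_elevation("985ft").value_m == pytest.approx(300.228)
    assert convert_verbatim_elevation("1616").value_m == 1616.0
    assert convert_verbatim_elevation("1627.000 m").value_m == 1627.0
    interval = convert_verbatim_elevation("15000–17000 ft")
    assert interval.kind == "interval"
    assert interval.min_m == pytest.approx(4572.0)
    assert interval.max_m == pytest.approx(5181.6)
    assert convert_verbatim_elevation("about sea level").kind == "unparseable"


@settings(derandomize=True, max_examples=200)
@given(st.floats(0, 1e4, allow_nan=False), st.floats(0, 1e4, allow_nan=False))
def test_depth_summary_center_and_deviation(a, b):
    lo, hi = min(a, b), max(a, b)
    center, accuracy = depth_summary(lo, hi)
    assert lo <= center <= hi
    assert accuracy >= 0
    # mean absolute deviation of the two endpoints, computed independently
    assert accuracy == pytest.approx((abs(lo - center) + abs(hi - center)) / 2)


def test_depth_summary_examples_and_invalid_range():
    assert depth_summary(10, 20) == (15, 5)
    assert depth_summary(7, 7) == (7, 0)
    with pytest.raises(ValueError):
        depth_summary(5, 3)


@pytest.mark.parametrize(
    "raw,processed,verdict",
    [
        ("Australia", "Mozambique", "mismatch"),
        ("Australia", "AU", "match"),
        ("Australia", "Australia", "match"),
        ("", "AU", "not_assessable"),
        ("Australia", "", "not_assessable"),
    ],
)
def test_country_assignment(raw, processed, verdict):
    assert audit_country(raw, processed).country_verdict == verdict


def _pair(i, orig, proc):
    return RecordPair(str(i), f"C.{i}", orig, proc)


def test_field_loss_totals_partition():
    pairs = (
        [_pair(i, {"identifiedBy": "A. Person"}, {"identifiedBy": ""}) for i in range(17)]
        + [_pair(i + 100, {"identifiedBy": "B. Person"}, {"identifiedBy": "B. Person"})
           for i in range(43)]
        + [_pair(i + 200, {"identifiedBy": "  "}, {"identifiedBy": ""}) for i in range(5)]
    )
    report = field_loss(pairs, "identifiedBy")
    assert (report.supplied, report.lost, report.retained, report.never_supplied) == (
        60, 17, 43, 5)
    assert report.lost + report.retained + report.never_supplied == len(pairs)
    assert report.loss_fraction == pytest.approx(17 / 60)


def test_field_loss_total_and_absent_column():
    full_loss = field_loss(
        [_pair(i, {"identifiedBy": "X"}, {}) for i in range(100)], "identifiedBy"
    )
    assert full_loss.loss_fraction == 1.0
    assert full_loss.term_missing_in_processed
    empty = field_loss([_pair(1, {"identifiedBy": ""}, {"identifiedBy": ""})], "identifiedBy")
    assert empty.supplied == 0 and empty.loss_fraction == 0.0
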