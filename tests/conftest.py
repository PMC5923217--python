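"""Shared fixtures: synthetic datasets and a full-pipeline audit runner."""

from __future__ import annotations

import os

import pytest

from dwcaudit.change_classifier import audit_records, tabulate_changes
from dwcaudit.dwc_io import dedupe_by_modified, read_ala_table, read_gbif_dwca
from dwcaudit.synthetic_data import (
    SyntheticManifest,
    example_study_spec,
    generate_paired_dataset,
    write_fixture,
)
from dwcaudit.value_audits import (
    field_loss,
    summarize_agents,
    summarize_countries,
    summarize_dates,
    summarize_datums,
)


def run_full_audit(spec: SyntheticManifest, dialect: str, workdir) -> dict:
    """Generate, write, re-read and audit a synthetic dataset; return the
    measured tallies in the same shape as the manifest."""
    dataset = generate_paired_dataset(spec, dialect=dialect)
    if dialect == "ALA_TSV":
        path = os.path.join(workdir, "fixture.tsv")
        write_fixture(dataset, path)
        pairs = read_ala_table(path)
    else:
        path = os.path.join(workdir, "dwca")
        write_fixture(dataset, path)
        pairs = read_gbif_dwca(path)
    deduped = dedupe_by_modified(pairs)
    names_result = audit_records(deduped)
    tally = tabulate_changes(names_result.changes, names_result.examined)
    measured = {
        "n_read": len(pairs),
        "n_after_dedupe": len(deduped),
        "duplicates_removed": deduped.removed,
        "classification_errors": names_result.errors,
        "name_change_counts": dict(tally.rows),
        "date_outcome_counts": dict(summarize_dates(deduped)),
        "agent_pattern_counts": dict(summarize_agents(deduped)),
        "datum_verdict_counts": dict(summarize_datums(deduped)),
        "country_mismatches": summarize_countries(deduped).get("mismatch", 0),
        "field_loss_counts": {
            term: field_loss(deduped, term).lost
            for term in dataset.manifest.field_loss_counts
        },
    }
    return {"manifest": dataset.manifest, "measured": measured}


@pytest.fixture
def full_audit():
    return run_full_audit


@pytest.fixture
def small_study_spec():
    """A reduced study spec: the standard defect mix at 300 records."""
    spec = example_study_spec(seed=7, n_records=1000)
    spec.n_records = 300
    # thin the heavy date rows so everything fits in 300 records
    spec.date_outcome_counts = {
        k: max(1, v // 4) for k, v in spec.date_outcome_counts.items()
    }
    spec.field_loss_counts = {k: v // 2 for k, v in spec.field_loss_counts.items()}
    return spec
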