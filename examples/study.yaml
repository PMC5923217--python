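# Desk-scale synthetic study: defect mix loosely mirroring an audited
# museum dataset. Seed comes from the command line.
agent_pattern_counts:
  added_initial: 4
  changed_ok: 10
  conjunction_failure: 5
  initial_comma: 3
  initial_reversal: 4
  null_replacement: 8
  surname_ending_truncation: 3
country_mismatches: 5
date_outcome_counts:
  DATETIME_FRAC_TZ|excluded: 10
  DATETIME_TZ|accepted_full: 5
  INTERVAL_DD|accepted_start_only: 12
  INTERVAL_DD|excluded: 2
  INTERVAL_MD|accepted_start_only: 4
  INTERVAL_YMD|accepted_start_only: 3
  INTERVAL_YM|excluded: 2
  INTERVAL_Y|excluded: 2
  MALFORMED|not_applicable: 3
  YMD|accepted_full: 80
  YMD|excluded: 30
  YM|excluded: 15
  Y|excluded: 30
datum_verdict_counts:
  deleted: 4
  incorrect_mapping: 5
  unmapped: 2
duplicate_pairs: 12
field_loss_counts:
  habitat: 10
  identifiedBy: 30
  locality: 25
n_records: 1000
name_change_counts:
  amended|genus for genus: 2
  amended|species for species: 15
  deleted|genus: 1
  deleted|species: 2
  down_match|genus to subgenus: 3
  down_match|species to subspecies: 6
  fail_match|species for plant: 1
  subgenus|added to species: 8
  subgenus|deleted from species: 5
  swap_match|genus for genus: 4
  swap_match|species for species: 35
  up_match|species to family: 15
  up_match|species to genus: 40
  up_match|subgenus to genus: 3
  up_match|subspecies to species: 12
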