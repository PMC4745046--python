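# Column mapping for the study's supplementary spreadsheet
# (pnas.1409497111.sd01.xlsx).  The headers below are a best guess and may
# need adjustment to the actual sheet layout; any header not mapped to a
# metadata column is treated as a taxon count column.
sheet: 0
column_map:
  Subject: subject_id
  Day_of_life: day_of_life
  Gestational_age_at_birth: gestational_age_at_birth
  Postconceptional_age: postconceptional_age
  Antibiotics: antibiotics
  Room: open_room
units:
  postconceptional_age: weeks
  antibiotics: percent_of_days
min_fraction: 0.01
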