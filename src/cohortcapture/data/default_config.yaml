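# Default pipeline configuration: a synthetic referral population with
# eleven partially overlapping clinical databases.
population:
  n_patients: 37947
  disease_prevalence: 0.344
  seed: 0
  year_range: [2007, 2023]

gold_standard:
  n: 2800
  min_databases: 2
  split_fraction: 0.3
  target_prevalence: 0.75

# Per-database flagging profiles: coverage, sensitivity within covered
# patients, target precision at the population prevalence, and whether
# the database is a clinician-curated registry (membership implies flag).
databases:
  ICD10 Codes:                       {coverage: 0.9548, sensitivity: 0.95, precision: 0.96, registry: false}
  OPCS4 Codes:                       {coverage: 0.3260, sensitivity: 0.17, precision: 0.86, registry: false}
  Patient Portal:                    {coverage: 0.5095, sensitivity: 1.00, precision: 0.97, registry: true}
  EPR IBD Registry:                  {coverage: 0.6798, sensitivity: 1.00, precision: 0.97, registry: true}
  Cytokine Modulator Prescriptions:  {coverage: 0.2357, sensitivity: 1.00, precision: 1.00, registry: false}
  Flare Calls:                       {coverage: 0.6012, sensitivity: 1.00, precision: 0.87, registry: false}
  IBD Clinic Appointments:           {coverage: 0.7905, sensitivity: 0.70, precision: 0.80, registry: false}
  Calprotectin > 50:                 {coverage: 0.6345, sensitivity: 0.70, precision: 0.80, registry: false}
  Endoscopy Records:                 {coverage: 0.8790, sensitivity: 0.70, precision: 0.95, registry: false}
  Clinical Letters:                  {coverage: 0.9450, sensitivity: 0.99, precision: 0.79, registry: false}
  Histopathology Records:            {coverage: 0.6024, sensitivity: 0.89, precision: 0.73, registry: false}
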