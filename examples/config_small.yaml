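# Runtime-scaled pipeline configuration for the CLI worked example.
# Structural parameters (trait counts, thresholds, separability) match the
# full-scale defaults; only cohort and variant counts are reduced.
sim:
  n_variants: 700
  cohorts:
    - {cohort_id: disc_a, n_cases: 150, n_controls: 150}
    - {cohort_id: disc_b, n_cases: 160, n_controls: 160}
    - {cohort_id: trial, n_cases: 120, n_controls: 0, role: trial}
  n_traits: 8
  n_comorbid: 4
  n_shared: 12
  n_focal_extra: 40
seed: 11
k_range: "2:6"
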