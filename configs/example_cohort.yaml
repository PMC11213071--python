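# Example synthetic cohort for the bundled end-to-end run.
# Sizes are a scaled-down cohort that keeps every analysis stage exercised
# while the full pipeline completes in well under five minutes.
cohort:
  n_t21: 120
  n_d21: 60
  age_range: [0.5, 57.0]
  sex_ratio: 0.5
  n_sources: 3

effects:
  elevated_analytes:
    TNF-a: 1.0
    IL-6: 0.8
    CRP: 0.6
    IP-10: 0.7
  age_slopes:
    CRP: 0.01
  batch_sd: 0.25
  isg_fold_changes:
    ISG01: 2.0
    ISG02: 1.8
    ISG03: 1.7
    ISG04: 1.6
    ISG05: 1.6
    ISG06: 1.5
  enriched_antigens:
    AG001: 9.0
  cluster_logit_shifts:
    CL01: -0.7
    CL02: 0.5
  treatment_effect: 0.7

markers:
  n_analytes: 24
autoantigens:
  n_antigens: 60
clusters:
  n_clusters: 12
trial:
  n_participants: 10
  trigger_prob: 0.1
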