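# Two-subpopulation cohort: 93% low-risk, 7% high-risk, 70 simulated years.
seed: 1
cohort:
  n: 1000
  years: 70
  subpopulations:
    - preset: low_risk
      weight: 0.93
    - preset: high_risk
      weight: 0.07
output_dir: .
log_level: INFO
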