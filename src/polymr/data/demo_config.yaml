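# Small end-to-end demonstration run.
schema_version: 1
sim:
  n_individuals: 2000
  n_variants: 80
  n_causal: 40
thresholds: [1.0, 0.05]
adjustments: [crude, primary]
analyses: [descriptive, observational, one_sample_mr, diagnostics]
seed: 7
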