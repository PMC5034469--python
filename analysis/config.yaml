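# Study configuration for the synthetic twin-cohort age-EWAS.
# Unlisted keys take the package defaults (see agewas.simdata.SimConfig and
# agewas.pipeline.PipelineConfig); the defaults are the desk-scale study
# conditions described in docs/methods.md.
sim:
  seed: 0
alpha: 0.05
overlap_fraction: 0.1
rate_threshold: 10.0
n_permutations: 1000
normalisation: zscore
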