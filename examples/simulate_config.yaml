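# Two latent response categories with clustered dependence (pairs, r = 0.3).
population:
  categories:
    - label: responders
      weight: 0.4
      arm_laws:
        - {family: normal, params: {mean: 0.0, sd: 1.0}}
        - {family: normal, params: {mean: 0.8, sd: 1.0}}
    - label: non-responders
      weight: 0.6
      arm_laws:
        - {family: normal, params: {mean: 0.0, sd: 1.0}}
        - {family: normal, params: {mean: 0.0, sd: 1.0}}
  dependence:
    mode: clustered
    cluster_size_law: {kind: constant, params: {value: 2}}
    intra_cluster_correlation: 0.3
design:
  allocation_scheme: permuted-block
  block_length: 4
  sample_size_regime: dropout
  retention: 0.9
n_subjects: 120
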