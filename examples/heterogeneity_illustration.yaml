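# Illustrative many-category population with a bimodal, dormancy-like
# survival surrogate in one stratum. Purely schematic -- no claim of
# biological fidelity.
population:
  categories:
    - label: cured
      weight: 0.5
      arm_laws:
        - {family: truncated-normal, params: {mean: 9.0, sd: 1.0, lo: 0.0, hi: 10.0}}
        - {family: truncated-normal, params: {mean: 9.0, sd: 1.0, lo: 0.0, hi: 10.0}}
    - label: dormant-metastases
      weight: 0.3
      arm_laws:
        - {family: tabulated, params: {values: [2.0, 8.0], probs: [0.6, 0.4]}}
        - {family: tabulated, params: {values: [2.0, 8.0], probs: [0.4, 0.6]}}
    - label: aggressive
      weight: 0.2
      arm_laws:
        - {family: truncated-normal, params: {mean: 2.0, sd: 1.0, lo: 0.0, hi: 10.0}}
        - {family: truncated-normal, params: {mean: 3.0, sd: 1.5, lo: 0.0, hi: 10.0}}
design:
  allocation_scheme: complete-balanced
n_subjects: 200
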