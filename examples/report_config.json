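{
  "scenarios": [
    "iid-normal-null",
    "iid-normal-null-permutation",
    "iid-normal-shift",
    "clustered-null-parametric",
    "clustered-null-permutation",
    "heterogeneous-null"
  ],
  "n_reps": 2000
}
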