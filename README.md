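# permtrial

Randomization inference, Berry–Esseen p-value error bounds, and
operating-characteristic simulation for two-arm randomized trials.

The package quantifies how violations of the textbook assumptions behind
trial inference — heterogeneous responses, within-cluster dependence,
random sample size, ignored randomization — distort p-values and type-I
error, and implements the remedies:

- **permutation (randomization) p-values** under the strong null, exact
  over every admissible allocation of the scheme actually used, or
  Monte Carlo with the add-one estimator;
- **permutation-averaged parametric p-values**: the mean of normal-tail
  p-values over all admissible allocations with responses held fixed;
- **Berry–Esseen uncertainty intervals** for parametric p-values,
  `0.5·C·n^(−1/2)` per arm, with guaranteed-decimal-digit and minimal-n
  calculators.

## Layout

| module | contents |
| --- | --- |
| `permtrial.distributions` | response laws (normal, bernoulli, truncated-normal, two-point, uniform, tabulated, constant), integer laws, moment ratio `C` |
| `permtrial.population` | category mixtures, clustered equicorrelation, cohort sampling with once-drawn potential outcomes |
| `permtrial.engine` | randomization schemes (simple coin, complete balanced, permuted block), sample-size regimes (fixed, Poisson total, dropout, event-driven), allocation enumeration |
| `permtrial.inference` | parametric / permutation-exact / permutation-MC / permutation-averaged-parametric p-values |
| `permtrial.bounds` | Berry–Esseen epsilons, p-value intervals, `min_n_for_tolerance`, `guaranteed_decimal_digits`, empirical KS verification |
| `permtrial.experiments` | operating-characteristic scenarios, worked-example demos, reproducible report bundles |

## CLI

```sh
# sample a cohort and run one trial
permtrial simulate --config examples/simulate_config.yaml --seed 1 --out out/

# re-analyze a subject table (subject_id, [cluster_id], arm, response)
permtrial test --data out/trial.tsv --method permutation-exact --sided two-sided

# Berry–Esseen calculators
permtrial bounds --n1 400 --n0 400 --c1 1 --c0 1 --p 0.03 --tolerance 0.005

# operating characteristics of a preset scenario
permtrial oc --scenario clustered-null-parametric --n-reps 2000 --seed 1

# worked examples
permtrial demo averaging
permtrial demo random-n --expected-n 200

# scenario bundle with manifest (bit-exact replay under the same seed)
permtrial report --config examples/report_config.json --seed 1 --out report/
```

Population/design configuration schema is documented in
`permtrial/config.py`; JSON and YAML are both accepted.

## Notes on conventions

- The normalized difference defaults to the unpooled (Welch-style)
  standardization; pooled is available via `realize_trial(..., pooled=True)`.
- Two-sided permutation extremeness is `|statistic| >= |observed|`; ties
  count as extreme, keeping the test exact.
- Monte-Carlo permutation p-values use the add-one estimator
  `(b + 1)/(m + 1)` and can never be zero.
- The iid Berry–Esseen constant is 0.5; the generalized
  (non-identically-distributed) constant defaults to 0.56. Both are
  configurable and echoed in reports.
- The two-arm combined p-value error is the **sum** of per-arm KS bounds:
  for independent arm means, `sup_x |F_{A+B}(x) − Φ_{A+B}(x)|` is bounded
  by the sum of the arms' sup-distances (triangle inequality through the
  intermediate convolution with one arm replaced by its normal
  approximation), so the sum is a valid upper bound — reported as an upper
  bound only.
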