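# rankggm

Bayesian Gaussian-copula graphical models with extended rank likelihood,
built for sex-stratified two-wave network analyses of mixed-type cohort
data (zero-inflated biomarkers, ordinal scales, binary genotypes,
continuous scores).

The package provides:

- **`rankggm.cohort`** — variable schema, validated CSV round-trip,
  sex-stratified partitioning, descriptive summaries.
- **`rankggm.simulate`** — a deterministic two-wave cohort generator with a
  known latent partial-correlation network per sex, configurable margins
  (zero-inflated lognormal, count, Gaussian, ordinal-cutpoint, Bernoulli),
  MCAR missingness, and logistic informative attrition.
- **`rankggm.copula`** — the core estimator: Gibbs sampling over
  rank-constrained latent Gaussians and a conjugate Wishart precision
  update, posterior-predictive imputation of missing cells in-sampler, and
  credible-interval edge selection on the partial-correlation draws.
  Only ranks enter the likelihood, so results are invariant (bit-exactly,
  at fixed seed) under strictly monotone transforms of any margin.
- **`rankggm.compare`** — per-edge posterior differences between two
  groups with equal-tailed CIs, hypothesis formation from significant
  differences, and one-sided posterior-probability confirmation
  (threshold 0.95, ties split).
- **`rankggm.pipeline`** — exploratory/confirmatory orchestration,
  paired between-wave t-tests, completer/dropout comparisons,
  Procrustes-averaged force-directed layouts, and network figures.

The Gibbs sweep is JIT-compiled with numba; a full 11-node fit
(n=450, 5 500 sweeps) takes a few seconds after the one-off compilation.

## CLI

```sh
# deterministic two-wave synthetic cohort (shipped reference scenario)
rankggm simulate --seed 3 --n-per-sex 450 --out runs/sim

# exploratory wave-1 analysis: fit per sex, select edges, compare, form hypotheses
rankggm explore --wave1 runs/sim/wave1.csv --seed 11 --out runs/explore

# confirmatory wave-2 analysis of the carried-forward hypotheses
rankggm confirm --wave2 runs/sim/wave2.csv \
    --hypotheses runs/explore/hypotheses.yaml --seed 21 --out runs/confirm

# robustness checks: paired between-wave t-tests, completer comparison
rankggm check --wave1 runs/sim/wave1.csv --wave2 runs/sim/wave2.csv --out runs/check
```

All artifacts are plain CSV/YAML/SVG and byte-reproducible from the
configuration and seeds.

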