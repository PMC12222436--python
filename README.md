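# cpue-ssm

Hierarchical Bayesian state-space modelling of long-term, multi-taxon
fishery catch/effort panels.

The model estimates each taxon's latent log-CPUE (catch per fisher per
year) as a random walk whose drift switches between predefined stressor
eras ("periods") and responds to the per-period temperature anomaly.
Effort (number of fishers) is itself latent — Poisson counts on a log
random walk — so years with missing effort records are imputed coherently.
Taxon-level coefficient vectors `(beta1, beta2, beta3, gamma)` share a
multivariate normal community prior, giving community-level average growth
rates per period as the posterior of its mean vector. A post hoc stage
compares life-history traits between early- and late-declining taxa with a
Gaussian mixed model (random intercept per subfamily, ML fit).

Because the motivating fishery's records are not publicly deposited, the
package ships a first-class synthetic-data generator that runs the exact
generative model forward with known parameters; all testing and validation
is built on it (parameter recovery, Kalman-smoother oracles, convergence
contracts).

## Layout

| module          | contents                                                                |
| --------------- | ----------------------------------------------------------------------- |
| `covariates`    | period schemes, one-hot period indicators, per-period temperature anomalies, lagged drift design |
| `synthetic`     | seeded generative emulation of the panel (`simulate_community`, group-structured preset) |
| `model`         | zero-floor catch preprocessing, drift/climate terms, full `log_joint`, priors |
| `sampler`       | batched blocked Gibbs sampler (FFBS states, conjugate coefficients/variances/hyper-layer, Metropolis effort layer, Kalman-marginal variance moves) |
| `inference`     | `fit`, R-hat (classic / split / rank-normalized), period & community growth summaries, CPUE trajectories |
| `traits`        | decline-timing group assignment, rank transform, mixed-model trait comparison |
| `io`, `pipeline`, `cli` | CSV readers/writers with validation, end-to-end driver, command line |

## CLI

```sh
cpue-ssm simulate --out data/ --seed 1
cpue-ssm fit --data data/ --out posterior.npz --seed 1 \
    --sampler sampler.yaml --model-config model.yaml
cpue-ssm summarize --posterior posterior.npz --out tables/ --plots
cpue-ssm traits --growth tables/growth_summary.csv --out trait_results.csv
cpue-ssm run-all --out run/ --seed 1          # demo pipeline, writes manifest
```

`model.yaml` may set `floor` (zero-catch replacement, grams) and
`period4_starts` (mapping taxon -> first restoration year). `sampler.yaml`
takes `n_chains`, `n_warmup`, `n_draws`, `thin`. Input CSVs are
long-format: `catch.csv` (taxon, year, catch_g), `effort.csv`
(year, n_fishers; blank = missing), `temperature.csv` (year, temp_c).

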