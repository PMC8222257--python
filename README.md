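# pollinet

Bayesian reconstruction of bipartite plant–pollinator interaction networks
from noisy visitation count data.

Field surveys record how often each pollinator species was seen visiting each
plant species. Those counts conflate true ("preferred") interactions with
sampling effort, species abundances, and observation noise. `pollinet` models
the counts as Poisson variables whose means are
`C * sigma_i * tau_j * (1 + r * B_ij)` — effort `C`, relative abundances
`sigma`/`tau`, preference boost `1 + r`, and a latent binary incidence matrix
`B` with prior edge probability `rho` — then infers everything jointly:

- the binary structure is **marginalized analytically**, so a Hamiltonian
  Monte Carlo sampler (built in, no external PPL) draws the continuous
  parameters from their marginal posterior;
- per-pair **edge probabilities** are recovered in closed form given the
  parameters and averaged over draws;
- **posterior-predictive checks** (predictive mean matrix, residue,
  chi-squared discrepancy against `n_p * n_a` degrees of freedom) assess fit;
- network **metrics** (connectance, NODF nestedness, degree distributions,
  mean degrees, thresholded baselines, multi-site aggregation) can be
  computed on single networks or as full posterior distributions;
- a **synthetic-data module** generates ground-truth scenarios from the same
  generative model and runs parameter/edge recovery experiments.

## Command line

```bash
# simulate a synthetic visitation matrix (writes the true network alongside)
pollinet simulate --n-plants 8 --n-pollinators 21 --c 500 --r 40 --rho 0.25 \
    --seed 1 --out scratch/sim.csv

# fit: draws, edge probabilities, predictive check, metric distributions
pollinet fit scratch/sim.csv --out scratch/run --chains 4 --warmup 5000 \
    --draws 500 --seed 1

# convergence diagnostics for an existing draw archive (nonzero exit if trapped)
pollinet check scratch/run/draws.csv

# thresholded-baseline metrics for a matrix
pollinet metrics scratch/sim.csv -t 1

# sum matrices over the union of their species
pollinet aggregate site_a.csv site_b.csv --out combined.csv
```

Input format (`labeled_csv`): first row pollinator labels, first column plant
labels, integer counts in the cells. `--format weblife` accepts the Web of
Life matrix export (float-encoded integers, padded rows/columns tolerated).

## Python API sketch

```python
from pollinet import (
    SamplerConfig, sample_parameters, check_convergence,
    posterior_edge_matrix, predictive_mean, nodf,
)
from pollinet.io import load_visitation_matrix
from pollinet.metrics import posterior_metric

data = load_visitation_matrix("visits.csv")
draws = sample_parameters(data, config=SamplerConfig(), seed=1)
print(check_convergence(draws).summary())
edges = posterior_edge_matrix(draws, data)          # P(B_ij = 1 | M)
summary = predictive_mean(draws, data)              # lambda, residue, X^2
nodf_dist = posterior_metric(nodf, draws, data)     # posterior of nestedness
```

## Layout

| module | contents |
| --- | --- |
| `pollinet.model` | data types, likelihood, priors, stable marginal log posterior |
| `pollinet._hmc` | unconstrained transforms, gradients, adaptive HMC |
| `pollinet.inference` | sampler front end, diagnostics, edge probabilities, posterior averaging |
| `pollinet.assessment` | predictive means, residue, chi-squared discrepancy |
| `pollinet.metrics` | connectance, NODF, degree distributions, aggregation |
| `pollinet.synthetic` | scenario generators and recovery experiments |
| `pollinet.io`, `pollinet.run`, `pollinet.cli` | readers/writers, fit orchestration, CLI |
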