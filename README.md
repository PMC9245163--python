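# stcarclust

Bayesian spatio-temporal disease mapping with **clustering-based adjacency
modelling**: estimate areal disease risk while simultaneously identifying
clusters of areas whose risks differ sharply from their geographical
neighbours, by treating the neighbourhood matrix of a conditional
autoregressive (CAR) model as a parameter to estimate.

## Who this is for

Epidemiologists and spatial statisticians analysing areal-unit count panels
(observed counts `Y_it` and expected counts `E_it` for `n` areas over `T`
periods, e.g. yearly hospital admissions by small area).  Standard CAR
smoothing models force geographically adjacent areas toward similar risks,
which masks real discontinuities — a deprived high-risk district bordering
an affluent low-risk one.  This package estimates where those boundaries
are, with full posterior uncertainty, instead of assuming them away.

## Model

The data model is the Poisson log-linear specification

```
Y_it | E_it, R_it ~ Poisson(E_it R_it)
ln R_it = x_it' beta + phi_it + theta_t
```

with an AR(1) region-wide trend `theta_t` and, per period, a spatial surface
`phi_t ~ N(0, tau_t^2 Q(rho, W)^{-1})` under the Leroux CAR prior,
`Q(rho, W) = rho (diag(W1) - W) + (1 - rho) I`.  Because the partial
correlation between neighbours `(i, j)` is proportional to `rho w_ij`,
zeroing `w_ij` models a *discontinuity* between adjacent areas.

The method has two stages:

1. **Candidate construction** — eight classical clustering methods
   (k-means, k-medoids/PAM, four agglomerative linkages, divisive/DIANA,
   Gaussian-mixture EM), each for `k = 1..K` cluster counts, partition the
   estimated spatial residuals into risk levels; every partition induces a
   candidate `W` by severing borders between clusters.  Variant A builds one
   static candidate family (`(K-1)M + 1` matrices); variant B one per
   period (`(K-1)MT + 1`).
2. **Estimation** — a single MCMC run samples all model parameters *and*
   `W` (discrete uniform prior over the candidates) via a bespoke two-move
   Metropolis-Hastings step: change the cluster count within a window
   `s` for the same method, then change the method at the same count.
   The posterior mode of `W` is the estimated cluster structure.

Model presets: `ST-A`/`ST-B` (static/dynamic clusters, `rho` fixed at
0.99), `ST-A*`/`ST-B*` (`rho` estimated), `ST-N` (non-cluster border-sharing
reference).  See `docs/methods.md` for priors, update details and the
synthetic-data design.

## Worked example

Simulate a 257-area, 7-year panel with three static risk levels
(`Z = 1`: high/medium/low risks around `e`, 1, `1/e`), then fit the static
cluster model with `rho` estimated:

```python
import stcarclust as s

sc = s.SimulationScenario(case=1, Z=1.0, SF=1.0, rho_true=0.9,
                          n_areas=257, T=7, seed=7)
sim = s.simulate_dataset(sc)
samples, cands = s.fit_model(sim.data, sim.graph, model="ST-A*",
    config=s.ModelConfig(n_iter=10_000, burn_in=5_000, thin=10, seed=7))
summary = s.summarize(samples, sim.data, cands)
rmse, cov = s.rmse_and_coverage(sim.risk, summary.risk_median,
                                summary.risk_lower, summary.risk_upper)
print("modal W (method, clusters):", summary.w_mode_label[0])
print("cluster count mode (95% CrI):", summary.cluster_counts[0])
print("ARI vs truth: %.3f" % s.spatiotemporal_ari(sim.labels, summary.modal_partition))
print("risk RMSE: %.3f   95%% CrI coverage: %.3f" % (rmse, cov))
print("DIC: %.0f   pd: %.0f" % (summary.dic, summary.pd))
print("posterior median rho: %.4f   alpha: %.2f" % (summary.parameters["rho"],
                                                    summary.parameters["alpha"]))
```

prints

```
modal W (method, clusters): (1, 3)
cluster count mode (95% CrI): (3, (3, 3))
ARI vs truth: 1.000
risk RMSE: 0.053   95% CrI coverage: 0.981
DIC: 13366   pd: 259
posterior median rho: 0.9999   alpha: 0.36
```

The posterior mode of `W` is the k-means (`c = 1`) three-cluster candidate —
exactly the generating structure (adjusted Rand index 1 against the truth) —
risk estimates are accurate (RMSE 0.053 on risks spanning ~0.4–3) with
near-nominal interval coverage, and the spatial dependence parameter is
estimated near 1 because, once the discontinuities are encoded in `W`,
the surviving neighbour pairs really are strongly correlated.

The same pipeline is available from the shell:

```sh
stcarclust simulate --case 1 --Z 1 --SF 1 --rho 0.9 --seed 1 --out sim/
stcarclust fit --counts sim/counts.csv --adjacency sim/adjacency.csv \
               --model "ST-A*" --out fit/
stcarclust evaluate --fit-dir fit/ --truth sim/truth.csv
```

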