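# Methods

## Model

`stcarclust` estimates spatio-temporal disease risk on `n` areal units over
`T` periods from observed counts `Y_it` and expected counts `E_it` (from
indirect standardisation), via the Poisson log-linear model

    Y_it | E_it, R_it ~ Poisson(E_it R_it)
    ln R_it = x_it' beta + phi_it + theta_t .

`theta = (theta_1, ..., theta_T)` is a region-wide temporal trend following
a Gaussian AR(1) process (`theta_1 ~ N(0, sigma2)`,
`theta_t | theta_{t-1} ~ N(alpha theta_{t-1}, sigma2)`, `alpha ~ U(0,1)`,
`sigma2 ~ InvGamma(1, 0.01)`).  Each period has its own spatial surface
`phi_t ~ N(0, tau_t^2 Q(rho, W)^{-1})` under the Leroux CAR prior with
precision `Q(rho, W) = rho (diag(W1) - W) + (1 - rho) I`,
`tau_t^2 ~ InvGamma(1, 0.01)` and `rho ~ U(0,1)` (or fixed at 0.99).

The distinguishing feature is that the binary neighbourhood matrix `W` is
**not** fixed at the border-sharing specification.  Because the partial
correlation between neighbouring random effects is proportional to
`rho * w_ij`, setting `w_ij = 0` for a geographically adjacent pair models
them as conditionally independent — a discontinuity (cluster boundary) in
the risk surface.  `W` is therefore treated as a model parameter with a
discrete uniform prior over a candidate set constructed in a first stage,
and estimated within the MCMC.

### Stage 1 — candidate construction

Spatial residuals are estimated as
`phi~_it = ln(Y*_it / E_it) - x_it' beta^`, with `beta^` the ML Poisson fit
(offset `ln E`) under working independence; `Y* = max(Y, 0.5)` applies a
continuity correction to zero counts in the log-ratio only (the ML fit uses
the true counts; the constant 0.5 is configurable).  Eight clustering
methods (k-means, PAM k-medoids, agglomerative centroid/complete/average/
Ward, DIANA divisive, Gaussian-mixture EM; single linkage excluded for its
chaining behaviour) are each run for `k = 2..K` cluster counts on

  * **variant A**: the `n x T` residual profiles (one static structure), or
  * **variant B**: each period's length-`n` residual vector separately.

Each partition induces a candidate matrix by zeroing every border between
areas in different clusters, giving `(K-1)M + 1` candidates (variant A) or
`(K-1)MT + 1` (variant B) after collapsing all `k = 1` solutions onto the
single border-sharing matrix.  Clustering operates on feature values only;
methods use Euclidean distance, seeded initialisations, and hard assignment
by maximum posterior responsibility for EM (full covariance for `d > 1`,
spherical for `d = 1`).  Features are not standardised (residuals are
already on the log-risk scale).  If a method returns fewer than `k`
non-empty clusters the partition is kept and still indexed under `(c, k)`,
preserving the candidate-set size.  Duplicate matrices arising at `k >= 2`
are retained as separate prior atoms.  Labels are canonicalised by ordering
clusters on their mean residual (label 1 = lowest risk level), which makes
partitions reproducible and comparable across methods and periods.

### Stage 2 — MCMC

Metropolis-within-Gibbs, sweep order: `beta` -> `phi` (element-wise) ->
centring -> `theta` -> centring -> `tau_t^2` -> `(sigma2, alpha)` -> `rho`
-> `W`.  Specifics:

* `phi_it`: element-wise Gaussian random-walk MH against the Poisson cell
  likelihood times the Leroux full conditional (compiled inner loop).
* `theta_t`: element-wise random-walk MH against the AR(1) prior (with the
  `theta_{t+1}` term) and the likelihood aggregated over areas.
* `tau_t^2`: exact conjugate draw `InvGamma(a + n/2, b + phi_t'Q phi_t/2)`.
* `sigma2`: conjugate draw; `alpha`: its exact Gaussian full conditional
  truncated to [0,1], drawn by inverse-CDF sampling.
* `rho`: random-walk MH on the logit scale with Jacobian, avoiding boundary
  sticking near 1.  Fixed-`rho` variants use 0.99 exactly, never 1, so
  candidates containing singleton (neighbourless) clusters stay proper.
* `W`: two discrete moves per sweep, each with its own accept/reject.
  Move 1 proposes a cluster count uniformly within +/- `s` (default 2) of
  the current `k` for the same method, with the asymmetric-window Hastings
  correction `|win(k)| / |win(k'))|` at the `k` boundaries; move 2 proposes
  a different method at the same `k` (symmetric).  The acceptance ratio
  reduces to the CAR log-density difference (likelihood and the uniform
  prior cancel), summed over periods for variant A and per period for
  variant B.  The border state keeps a latent method label so move 1 is
  defined from `k = 1`.  Log-determinants use eigenvalues of
  `diag(W1) - W`, computed once per candidate at assembly:
  `log det Q = sum_i log(rho lambda_i + 1 - rho)`.

After every sweep the per-period means of `phi` are absorbed into
`theta_t` and the mean of `theta` into the intercept, leaving the linear
predictor unchanged (zero-mean centring for identifiability).  Proposal
step sizes adapt every 100 burn-in iterations toward ~45% acceptance and
are frozen afterwards.  Chains are initialised at the observed log-SIR
decomposition (intercept at `ln(sum Y / sum E)`, `theta` at per-period
means, `phi` at the centred remainder) with `W` at the border-sharing
matrix; initialising `phi` at the data rather than zero avoids the
variance-collapse trap in which small `tau^2` and flat `phi` lock each
other near zero.

Model presets: **ST-A/ST-B** (variants A/B, `rho` fixed at 0.99),
**ST-A\*/ST-B\*** (`rho` estimated), **ST-N** (non-cluster reference:
variant A with the candidate set restricted to the border-sharing matrix,
`rho` estimated).

### Summaries

`W` is summarised by its posterior mode (pooled over chains; ties broken by
the smaller effective number of parameters computed on the tied subsets);
other parameters by posterior medians with 95% equal-tailed intervals.
Cluster counts are reported as the modal `k` with an equal-tailed 95%
interval per period.  DIC uses the plug-in deviance at the posterior mean
of the linear predictor (well defined across `W` values);
`pd = mean(D) - D(plug-in)`.  Convergence is monitored by Geweke z-scores
(first 10% vs last 50%, spectral variance with a Bartlett window).

## Synthetic data

No real study data ships with the package, so the generator emulates the
conditions of an urban respiratory-disease panel:

* **Geography**: a near-square rook lattice (257 areas = 16x16 plus one
  appended cell) standing in for the real polygon map.  It reproduces the
  scale and planarity of the real geography, not its irregular contiguity
  (degree distribution, river-split disconnection) — conclusions about
  adjacency-specific behaviour therefore transfer only approximately.
* **Expected counts**: per-area truncated log-normal (median 74.09, range
  12.61–160.15, log-sd 0.5), constant over periods, divided by a scale
  factor SF in {1, 2, 4} to emulate progressively rarer diseases.
* **Cluster template**: deterministic contiguous blobs covering ~20% of
  areas at elevated and ~20% at reduced risk; the piecewise-constant means
  `mu_it` take values in {-Z, 0, Z}.  Case 1 keeps the template fixed;
  Case 2 reassigns a random 3% of areas per period (cumulative drift) —
  the per-period flip fraction is a configurable knob.
* **Effects**: `theta` from the AR(1) model with `alpha = 0.9`,
  `sigma2 = 0.1`; `phi_t ~ N(mu_t, 0.001 * Q(rho, W_border)^{-1})` with
  `rho` in {0, 0.3, 0.6, 0.9}, drawn by Cholesky solves of the precision
  (dense at these sizes); `R = exp(phi + theta)`; `Y ~ Poisson(E R)`.
* A **model-free** mode fixes risks at {exp(Z), 1, exp(-Z)} with no random
  effects.

The full design grid comprises 30 sub-scenarios.  Passing tests on these
data show that the method recovers known cluster structure and risks under
its own assumptions (and under the model-free violation); they do not
certify behaviour under real-world features such as irregular adjacency,
population-driven heteroscedastic expected counts, or covariate
confounding.

## Evaluation metrics

Risk accuracy is measured by RMSE of posterior-median risks and by the
coverage of 95% credible intervals, both over all `(i, t)` cells.  Cluster
recovery is the adjusted Rand index (Hubert–Arabie) between the true level
partition and the stage-1 partition of the posterior-modal candidate.  The
single "over all time periods" number is the mean of per-period ARIs:
cluster identities are only meaningful within a period (a dynamic structure
carries no cross-period identity), and alternatives degenerate — raw
concatenation of per-period labels scrambles agreement for dynamic
structures, while making period-clusters globally distinct inflates the
chance baseline far above 0.

## Numerical and design choices

* Sparse matrices for all candidates; quadratic forms by sparse
  matrix-vector products; per-sweep caching of `phi_t' L phi_t`.
* Eigenvalues per candidate are computed once (dense symmetric solve;
  `n` up to a few thousand is assumed).
* `rho` is restricted to [0, 1) throughout; the intrinsic CAR limit is out
  of scope.
* Degenerate inputs: zero-variance features yield a single effective
  cluster; a zero denominator in the `alpha` conditional falls back to its
  uniform prior; non-finite log-posteriors abort the chain with diagnostics.
* Default run lengths in the replicated studies are 10,000 iterations with
  5,000 burn-in and thinning by 10, and 20 replicates per scenario in the
  acceptance script (5 in the test suite); posterior modes and medians are
  stable at these sizes for the default scenarios.
* Alternative variance priors InvGamma(0.001, 0.001) and
  InvGamma(0.5, 0.0005) are supported through `ModelConfig`.

## Known limitations

* Candidate structures are fixed after stage 1; the sampler cannot visit a
  partition no clustering method produced.
* The lattice geography and blob template are stand-ins; results tied to
  the real map (e.g. absolute DIC values) are not reproduced.
* Variant B clusters each period independently and can pick up
  noise-driven structures in short panels, as reflected in its wider
  cluster-count intervals.
* The non-cluster reference model fitted here is a faithful
  border-sharing restriction of the same sampler; see the study runner for
  its measured behaviour on clustered data.
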