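# Methods

## Data model

The unit of analysis is an areal panel: `K` spatial units observed over `T`
ordered periods, with event counts `y_kt`, trial counts `n_kt`
(`0 ≤ y_kt ≤ n_kt`, integers, every cell present) and unit-period
covariates. Time enters every model as the centred period rank
`t_p = p − (T+1)/2`, **not** rescaled by the range, so one unit of `t_p` is
one period and `exp(α)` is an odds ratio *per period* (per 5-year period in
the motivating application). Some CAR software internally rescales time to
`(t − t̄)/T`; that only rescales the trend slope, and results are
equivalent up to that factor — we keep the per-period scale because that is
the scale on which trend odds ratios are usually reported.

Covariates are standardized across units *within each period* (sample SD,
`K−1` denominator), so they express between-unit contrasts rather than
national secular trends. Standardization is idempotent and refuses
zero-variance columns.

The neighbourhood structure is a binary symmetric adjacency matrix `W`
(shared border → 1), read from a plain edge list or a GAL file. Ferry or
bridge connections are represented simply as extra edges in the input.
Isolated units are rejected; disconnected graphs are allowed with a
warning (CAR smoothing then acts per component).

## Models 1–2: binomial trend GLMs

Aggregated binomial logistic regression maximizing
`Σ_kt [y_kt η_kt − n_kt log(1+e^{η_kt})]` by IRLS with step-halving (the
log-likelihood never decreases), at most 100 iterations, convergence at
relative log-likelihood change `< 1e−10` or gradient max-norm `< 1e−8`.
Aggregated and individual-level fits have identical likelihoods for this
covariate structure, so aggregation loses nothing. Rank-deficient designs
fail naming the collinear columns; diverging coefficients (`|β̂| > 30`) are
reported as separation. Wald covariance comes from the observed
information at the optimum.

Residuals are defined on the empirical-logit scale with a 0.5 continuity
correction: `r_kt = log[(y_kt+0.5)/(n_kt−y_kt+0.5)] − η̂_kt`. This makes
`exp(r_kt)` literally the observed/expected odds ratio for the cell, the
quantity mapped in residual-OR reports, and handles `y = 0` and `y = n`
cells without special cases. Other residual types (Pearson, deviance)
would order units similarly but lack the direct OR reading; published
Moran's I values computed from an unspecified residual type are therefore
not expected to be reproduced numerically even on identical data.

## Moran's I

`I = (K/S0)·Σ w_kj z_k z_j / Σ z_k²` with binary weights
(`S0 = 2·|edges|`); row-standardized weights are available but off by
default, matching the binary-adjacency convention. Significance is
Monte-Carlo: uniform relabelings of the values over units, one-sided for
*positive* autocorrelation (the scientifically interpreted direction),
`p = (1+#{I_perm ≥ I_obs})/(1+n_perm)`, default 9999 permutations, so the
smallest attainable p is 1/10000. Reports attach the conventional stars
(\* <0.05, \*\* <0.01, \*\*\* <0.001). The statistic is affine-invariant;
constant vectors are rejected.

## Model 3: Leroux-CAR model with spatially varying linear trends

`logit p_kt = x_kt'β + φ_k + (α + δ_k)·t_p`, with independent Leroux CAR
priors on `φ` and `δ`: precision `[ρ(D−W) + (1−ρ)I]/τ²`, `ρ ~ U(0,1)`
(open at 1 to keep the prior proper), `τ² ~ InvGamma(1, 0.01)`, fixed
effects `N(0, 10⁵)`. The alternative prior set for sensitivity analysis is
`InvGamma(0.5, 0.005)` / `N(0, 2·10⁵)`.

### Sampler

Metropolis-within-Gibbs, one sweep per iteration in a fixed draw order
(elementwise β, then α, then φ by graph-colour class, δ by colour class,
Gibbs for τ²_φ and τ²_δ, Metropolis for ρ_φ and ρ_δ, then re-centring):

- **β, α** — elementwise Gaussian random-walk Metropolis against the
  binomial likelihood and the Gaussian prior.
- **φ_k, δ_k** — single-site random-walk Metropolis. The full-conditional
  prior for site `k` is Gaussian with mean
  `ρ Σ_j w_kj u_j / (ρ d_k + 1 − ρ)` and variance `τ²/(ρ d_k + 1 − ρ)`;
  the likelihood contribution for δ_k is scaled by `t_p`. Sites are
  updated one graph-colour class at a time: within a class no two sites
  are adjacent, so their full conditionals do not involve each other and
  the simultaneous vectorized update is *identical* to sequential
  single-site updates — a computational layout, not an approximation.
- **τ²** — conjugate Gibbs draw from
  `InvGamma(a + K/2, b + u'[ρ(D−W)+(1−ρ)I]u/2)`.
- **ρ** — random-walk Metropolis on the logit scale (with the Jacobian
  term); the determinant `½ Σ log(ρλ_i + 1 − ρ)` uses the once-computed
  eigenvalues of `D − W`.
- **Re-centring** — after every sweep the means of `φ` and `δ` are moved
  into the intercept and `α`. The likelihood only identifies
  `β₀ + mean(φ)` and `α + mean(δ)`; this convention pins "national level"
  and "national trend" to the across-unit mean and guarantees every
  retained draw of `φ` and `δ` has mean exactly 0.

Proposal scales adapt every 100 iterations during burn-in toward 40%
acceptance (univariate target) and are frozen afterwards, preserving
detailed balance in the retained portion. β and α are initialized at the
Model 2 MLE with proposal scales 2.4·SE; random effects start at zero.
Everything is driven by one seeded generator with a documented draw order,
so runs are exactly reproducible.

Default schedule: 26 000 iterations, 6 000 burn-in, thinning 10 → 2 000
retained draws, which keeps a full fit at `K=94, T=6` in the tens of
seconds on one core. A long production schedule
(1 050 000 / 50 000 / 50 → 20 000 retained) is available via
`McmcSettings.full_scale()` for final analyses.

### Summaries and diagnostics

Point estimates are posterior medians (means also reported for the trend),
intervals are equal-tailed 2.5–97.5% quantiles, both exponentiated to the
OR scale; the per-unit credible-interval span is reported as the
certainty-map quantity. Convergence is monitored with Geweke's diagnostic
(first 10% vs last 50% of the chain, segment-mean variances by batch means
with ≈√m batches) on the trend, hyperparameters and the log-posterior
trace. Model 3 residuals are plug-in empirical-logit residuals at the
posterior-median parameters, on the same scale as the GLM residuals so the
per-model Moran's I values are comparable.

`run_mcmc` exposes `sample_tau2` / `sample_rho` switches and an
`initial_state` for diagnostics; with an all-zero-trials panel the
likelihood is flat and the sampler draws from the prior, which is how the
prior-reproduction checks are run.

## Synthetic-data generator

`simulate_panel` draws from exactly the Model 3 generative family:
covariates iid standard normal per unit-period (playing the role of
already-standardized predictors), `φ` and `δ` from the centred Leroux CAR,
`y_kt ~ Binomial(n_kt, logistic(η_kt))`. Default scenario — the study
conditions the package targets:

- `K=94` units on a Denmark-like graph (Delaunay triangulation of random
  points pruned to mean degree ≈5, connected, deterministic per seed);
  `T=6` periods.
- `α = log 0.788` (the published national per-period trend OR used as
  scenario truth), `β₀ = −0.75` (mid-study national mortality ≈32%).
- Covariate effects: 0.30 log-odds/SD for mean AMI age (age is the
  dominant mortality determinant), ±0.05 for the sociodemographic shares.
- `ρ_φ = ρ_δ = 0.8`, `τ²_φ = 0.1`, `τ²_δ = 0.01`: visible spatial
  structure in levels, subtle structure in trends.
- Trial counts log-normal (σ=0.8) around mean 650 per cell, mimicking the
  skewed municipality-size distribution and national period totals in the
  tens of thousands; a fixed `n_trials` is available for calibration
  studies.
- Cluster scenario: a contiguous block (breadth-first growth from a random
  seed unit) gets `+0.074` added to `δ` — a decline ≈7.7% slower than
  national, the midpoint of the 4–12% band the motivating study reports.
- `spatial_covariates=True` mixes a unit-level CAR component into each
  covariate, with a high spatial share (0.9). Real sociodemographic
  covariates are smooth municipal characteristics: almost all of their
  between-unit variance is spatially structured, and very little is
  period-to-period noise. The share matters qualitatively: a low share
  injects substantial iid covariate noise into the trend-only model's
  residuals, which deflates its Moran's I by roughly as much as the
  spatial covariate signal inflates it — an artefact measured covariates
  do not have. With a high share the covariate-adjusted model removes
  genuinely *spatial* residual signal, reproducing the reported pattern
  that adjustment roughly halves residual Moran's I and making the
  ordering Model 1 ≥ Model 2 ≥ Model 3 meaningful. With the default iid
  covariates, adjusting mainly removes non-spatial variance and that
  ordering is not implied.
- The named `slow_decline_cluster` scenario combines the 10-unit cluster
  (`+0.074` on `δ`), a tight background trend field
  (`τ²_δ = 0.001`, marginal sd ≈ 0.02, so realized cluster declines span
  roughly 4-12% slower than national) and spatially structured
  covariates.

What the generator does **not** emulate: real municipality geometry and
population sizes, temporally correlated covariates, overdispersion beyond
the binomial, registry artefacts (diagnosis-source mix, boundary reforms),
or within-unit age structure. Passing recovery tests therefore shows the
inference machinery is correct for its own generative family, not that the
model is adequate for any particular real registry.

## Validation problem sizes

The test and acceptance suites run: oracle equivalence for Moran's I
(50 random graphs, brute-force double loop, 1e−10) and the GLM (20 random
panels against an independent second-order optimizer, 1e−6); permutation
type-I error at `K=94` over 500 null simulations with 999 permutations;
τ² Gibbs draws against the analytic inverse-gamma (KS on 10 000 draws);
prior-only CAR moment reproduction on a 6×6 lattice; trend recovery and
95% CI coverage over 10 replicates at `K=94, T=6, n_kt=500` with the
default 26 000/6 000/10 schedule; the cluster pattern and Moran ordering
over 10 replicates with a shortened 9 000/2 000/7 schedule; and prior
sensitivity at `n_kt=1000` with 16 000/4 000/10. These sizes keep a full
run on one core in minutes while leaving Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- Single-site random-walk updates mix slowly when `ρ` is very close to 1
  and `τ²` large; block or marginal updates would help but are not needed
  at `K ≈ 100`.
- `ρ` and `τ²` are only weakly jointly identified in the Leroux family at
  moderate `K` (a well-known property); component fields `φ`, `δ` and the
  trend `α` remain well identified, and prior sensitivity on those is what
  the sensitivity analysis checks.
- No overdispersion term: extra-binomial variation loads onto `φ`.
- The plug-in (posterior-median) residual understates posterior
  uncertainty; it is used only as a descriptive input to Moran's I.
- Moran's I on model residuals has a slightly non-nominal permutation null
  (residual exchangeability is approximate); the type-I calibration is
  checked on exchangeable noise.
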