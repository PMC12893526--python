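# Methods

This note records the statistical model, the synthetic-trial generator, the
numerical machinery, and the design choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Outcome model

Binary abstinence outcomes (prolonged abstinence by the Russell standard;
4-week point-prevalence abstinence) at 3 and 6 months are modeled per
outcome by one multilevel logistic regression spanning both follow-ups:

    logit P(Y_it = 1) = α + u_i + β_t·t + β_g·G + β_tg·t·G
                        + x_i'β_main + G·x_i'β_int

* `t` is a 6-month indicator, `G` the randomized allocation.
* `u_i ~ Normal(0, σ_u)` are participant-level adaptive intercepts linking
  the two repeated measurements; σ_u has a half-normal(0, 1) prior and the
  intercepts are sampled non-centered (`u_i = σ_u·ũ_i`, `ũ_i ~ N(0,1)`).
* Covariate coding: dummy contrasts against woman / snus daily /
  counseling "no" / primary-care recruitment; flags as 0/1; continuous
  covariates centered at the baseline-sample mean of all randomized
  participants but *not* rescaled, so coefficients are per natural unit
  (per year of age, per weekly cigarette).  Centering constants are frozen
  at fit time and reused for all counterfactual predictions.
* Only non-missing participant×timepoint records enter the likelihood;
  counterfactual predictions are made for every randomized participant.

Priors.  Interaction coefficients β_int share a Cauchy(0, τ) prior with a
single common τ; "standard normal hyperprior for a scale" is implemented as
half-normal(0, 1), since a scale must be positive.  A per-coefficient-τ
variant and a fixed Student-t(3, 0, 2.5) variant exist as options.  All
other non-intercept coefficients get Student-t(3, 0, 2.5); the fixed
intercept gets Normal(0, 1).  Interactions are covariate×group only — time
enters through one time and one time×group term; no covariate×time terms.

## Individualized effects

For each posterior draw and participant, δ(x_i) is the inverse-logit
contrast between the linear predictors with G=1 and G=0 at the requested
timepoint.  The posterior median per participant is the point estimate;
cohort summaries report the mean and SD of point estimates in percentage
points (×100).  Storage stays in probability-difference units.

Adaptive-intercept convention: δ is a function of baseline factors, so the
default sets u_i = 0 (the population-typical participant).  Two options
change this — `"draws"` uses each participant's posterior intercept draws,
`"marginal"` averages over Normal(0, σ_u) by 16-node Gauss–Hermite
quadrature.  The convention is recorded in output metadata because it
changes δ's scale (marginal effects are attenuated relative to the
conditional ones).

## Second-stage associations

Point estimates are standardized (mean 0, sample SD 1) and regressed on
baseline factors with a normal likelihood, Student-t(3, 0, 2.5) priors on
every coefficient, and a half-t(3, 0, 2.5) prior on the residual SD.  The
default enters all covariates jointly in one multivariable model; a
univariable-per-covariate mode ships behind a flag because the source
analysis does not state which was used.  Interaction models contain the two
mains plus their product built from the same codings (e.g. man ×
centered importance).  Every term is reported as posterior median, 2.5/97.5
percentile compatibility interval (linear-interpolation percentiles), and
Prob — 100 × the fraction of posterior mass strictly on the median's side
of zero; exact zeros count toward neither side.  Estimates are linear
coefficients on the standardized-effect scale and are never exponentiated.

The response is the *median* point estimate: posterior uncertainty in δ is
deliberately not propagated to stage two (see Limitations).

## Sampler

No-U-Turn HMC, implemented in the package with analytic gradients:
multinomial sampling over doubling trajectories, sub-tree U-turn checks on
the momentum sum, dual averaging toward a target acceptance statistic
(default 0.8), and Stan-style windowed estimation of a diagonal inverse
mass matrix (initial step-size buffer, doubling variance windows, terminal
buffer).  The initial inverse mass is seeded from the inverse Fisher
information of the design so that per-unit covariate scales do not cripple
early warmup.  Scales (σ_u, τ, residual SDs) are sampled on the log scale
with Jacobian terms, so their draws are strictly positive by construction.

The Cauchy interaction block is sampled on the natural scale ("centered"
parameterization): the Cauchy score −2β/(τ²+β²) is bounded, which keeps
step-size adaptation stable.  The textbook non-centered alternative —
β = τ·z·√v with z ~ N(0,1) and v ~ inverse-gamma(½, ½), whose marginal is
exactly Cauchy(0, τ) — is available as an option; its inverse-gamma density
wall produces divergent transitions whenever the adapted step size drifts,
which is why it is not the default.  Both parameterizations pass
finite-difference gradient checks in the test suite.

Defaults: 4 chains × 1000 warmup + 1000 draws, seeded; runs are
deterministic given the seed.  Reduced-scale defaults (n=400 cohort,
2 × 500+500) drive the command-line pipeline; `--paper-scale` switches to
n=1012 with 4 × 1000+1000.  Diagnostics (split R-hat ≤ 1.01, bulk ESS ≥ 400
per parameter, via ArviZ) are computed for every fit with ≥ 2 chains;
failures are reported, never silently altered.  Constant (zero-variance)
chains are flagged as degenerate instead of dividing by zero.  The test
suite demonstrates a fully passing run at n=200 with 4 × (800+1500) draws;
short replicate fits in the simulation studies intentionally run 1 chain
with a few hundred iterations and do not aim to pass these thresholds.

## Synthetic-trial generator

The generator emulates the structure of the motivating cessation trial —
the point is a known ground truth for every downstream stage, not a clone
of any real cohort.

* **Baseline covariates.**  Marginals are calibrated so large samples hit
  the configured targets exactly: truncated normals are *moment-matched*
  (the underlying location/scale solved so the truncated distribution has
  the target mean/SD — naive parameterization would, e.g., shift age by
  +0.8 years); 0–10 scores use moment-matched scaled Betas because no
  truncated normal on [0, 10] attains importance's mean 9.4 with SD 1.3
  (the moment pair is infeasible under an upper cap — the real item piles
  up at 10); lifetime quit attempts use a rounded lognormal with the
  rounding bias solved for, because a mean of 7.2 with SD 13.7 implies a
  coefficient of variation (1.9) no truncated normal on [0, ∞) can reach.
  Scores are continuous where the real items are discrete.
* **Age/years-smoking coupling.**  years_smoking = max(age − onset, 0)
  with a truncated-normal smoking-onset age whose parameters are solved by
  quadrature so the *marginal* of years_smoking hits mean 25.3/SD 14.6
  while years_smoking < age holds row-for-row.  This induces a strong
  (≈0.95) age–years correlation; the real correlation is unknown.
* **Joint distribution.**  Independence by default, with a Gaussian-copula
  hook for user-specified pairwise correlations (rank-based, attenuated
  through the marginal transforms).  The recruitment-setting split (80%
  online) is a simulator choice; the source reports no marginal for it.
* **Randomization.**  1:1 within randomly permuted blocks drawn uniformly
  from the permitted (even) sizes {2, 4}, separately per elective-surgery
  stratum; a truncated final block bounds per-stratum imbalance by the
  largest block size.
* **Outcomes.**  One adaptive intercept per participant per outcome
  (optionally shared across outcomes), Bernoulli draws from the logit
  truth, and closed-form per-participant δ (u = 0) stored as ground truth.
  The default truth (`nexit_like_dgp`) puts control prolonged abstinence
  near 8%, a group log-odds of 0.75 (≈7 percentage-point mean effect),
  a weaker point-prevalence effect (≈4 points), age/gender/importance/
  smoking-intensity interactions, and σ_u = 1.
* **Missingness.**  Follow-up response is logistic in arm and age per
  timepoint; defaults target ≈69%/66% (control/intervention) response at
  3 months and ≈64% at 6 months with a +0.02-per-year age coefficient at
  6 months only (older participants more likely to respond).  A missed
  timepoint blanks both outcomes (monotone within timepoint).

What passing tests on this generator do **not** show about real data: the
covariates are independent (save the age coupling), items are continuous,
missingness is ignorable by construction (logistic in observed arm and age
only), and both outcomes follow exactly the fitted model family.  Recovery
results here certify the machinery, not robustness to model misspecification.

## Simulation-study sizes

The acceptance-style studies use: fixed-effect recovery at n=4000 (10
replicates, truth: group +0.7, age×group +0.02, ±0.3 tolerance); ITE
recovery at n=2000 (truth–estimate correlation > 0.5); null-vs-strong
heterogeneity pairs at n=1000 (20 replicates); shrinkage comparison at
n=2000 (20 replicates × 2 priors); second-stage least-squares oracle at
n=5000 with priors inflated 1000-fold (±0.02); simulator fidelity at
n=50,000 with a Šidák-calibrated family bound over the 15 marginal checks.
Replicate fits use one chain with 125–250 warmup and draws each; at these
sizes the posterior-median Monte-Carlo error is a few hundredths on the
logit scale, an order below the recovery tolerances.

## Numerical choices and degenerate inputs

* Percentiles: NumPy's linear-interpolation convention throughout.
* SDs: sample convention (n−1); standardization uses the same.
* Prob ties: samples exactly 0 count toward neither side.
* Standardizing a zero-spread vector, empty posterior samples, mixed
  outcome×timepoint summaries, unknown outcomes/timepoints/covariates,
  rank-deficient or constant-column designs, and single-arm data all raise
  named errors; single-chain diagnostics raise instead of guessing.
* Divergence threshold: Hamiltonian error of 1000 (post-warmup divergences
  are counted and reported per chain).
* Seeds: all randomness flows from integer seeds through
  `numpy.random.SeedSequence` spawning; identical config + seed reproduces
  byte-identical artifacts, which the pipeline manifest checksums verify.

## Limitations

* **Stage-two intervals are descriptive, not calibrated.**  Because the
  second-stage response is the median-collapsed δ point estimate — a
  deterministic smooth function of the covariates once the outcome model is
  fixed — the stage-two regression has almost no residual variance and its
  compatibility intervals concentrate around the structural projection of
  whatever the outcome model estimated, noise included.  Under a truth with
  no interactions these intervals still exclude zero far more often than
  their nominal level suggests (the suite demonstrates this).  They
  describe the shape of the fitted δ surface; they are not frequentist
  tests of covariate–effect interaction, and uncertainty from stage one is
  not propagated.
* The cohort-level SD of δ point estimates *does* separate null from
  strongly heterogeneous truths (demonstrated pairwise in the suite), and
  relative statements across covariates remain meaningful.
* Associations are observational descriptions of a model surface even
  within a randomized trial; no causal interpretation of the covariate
  associations is intended.
* The sampler is a single-machine NUTS in NumPy; very large cohorts
  (≫10⁵ records) would need a compiled backend.
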