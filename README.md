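# trialite

Individualized treatment effects for two-arm randomized trials with binary
outcomes, built around the analysis design of a pragmatic SMS-based
smoking-cessation trial: a Bayesian multilevel logistic outcome model with
shrinkage priors on treatment–covariate interactions, per-participant
counterfactual effect distributions, and second-stage regressions that
describe which baseline factors the individualized effects track.

It is written for biostatisticians and trialists who want to go beyond the
average treatment effect of a two-arm trial and ask *who* benefited — and to
validate that whole workflow on synthetic trials with known ground truth
before touching real data.

## The model

For participant *i* with baseline covariates *xᵢ*, allocation *G* ∈ {0, 1}
and follow-up *t* (3 or 6 months), the observed binary abstinence outcome
*Yᵢₜ* is modeled as

```
logit P(Yit = 1) = α + ui + βt·t + βg·G + βtg·t·G + xi'βmain + G·xi'βint
```

with participant-level adaptive intercepts `ui ~ Normal(0, σu)`.  Priors:
Cauchy(0, τ) on every interaction coefficient with a common scale τ given a
half-normal(0, 1) hyperprior — a hierarchical shrinkage prior that pulls
weakly supported interactions to the null — Student-t(3, 0, 2.5) on the
other non-intercept coefficients, and standard normal priors on the fixed
and adaptive intercepts.  The model is estimated by the package's own
No-U-Turn sampler (multinomial NUTS with dual-averaging step-size and
windowed diagonal mass adaptation, analytic gradients), with split R-hat and
effective-sample-size diagnostics via ArviZ.

The individualized treatment effect is the counterfactual risk difference

```
δ(xi) = P(Yi = 1 | G = 1, X = xi) − P(Yi = 1 | G = 0, X = xi)
```

computed draw-wise from the posterior for **all** randomized participants
(the adaptive intercept is set to its center by default; participant-draw
and marginalized conventions are options).  Posterior medians of δ(xᵢ) are
the point estimates; their mean and SD in percentage points summarize the
cohort, and their standardized values are regressed on baseline factors
with Student-t(3, 0, 2.5) priors.  Each association is reported as the
posterior median, a 95% compatibility interval (2.5/97.5 percentiles), and
*Prob* — the percentage of posterior mass on the median's side of zero.

A synthetic-trial generator completes the package: moment-calibrated
baseline covariates matching the source trial's Table-1 marginals,
stratified permuted-block randomization (blocks of 2 and 4, stratified on
elective surgery), outcomes from a configurable logit-scale truth with
known per-participant δ, and arm/age-dependent follow-up nonresponse.

## Worked example

```python
from trialite import (GeneratorConfig, simulate_trial, nexit_like_dgp,
                      BayesianOutcomeModel, compute_ite, summarize_ite,
                      standardize_effects, fit_association)

config = GeneratorConfig.default()      # trial-like cohort, n=1012
dataset, truth = simulate_trial(config, nexit_like_dgp(), seed=1)

model = BayesianOutcomeModel(chains=2, warmup=300, draws=300, seed=2)
model.fit(dataset, "prolonged")

ite = compute_ite(model, dataset.baseline, timepoint="3mo")
s = summarize_ite(ite)
print(f"mean individualized effect {s.mean_pp:.1f} (SD {s.sd_pp:.1f}) percentage points")

z = standardize_effects(ite.point_estimates)
for est in fit_association(z, dataset.baseline, ["age", "gender", "importance"], seed=3):
    print(f"{est.term:12s} {est.median:+.3f} ({est.lower:+.3f} to {est.upper:+.3f})  Prob {est.prob:.1f}%")
```

prints

```
mean individualized effect 6.3 (SD 7.0) percentage points
age          +0.055 (+0.052 to +0.057)  Prob 100.0%
man          +0.290 (+0.198 to +0.381)  Prob 100.0%
importance   +0.220 (+0.196 to +0.245)  Prob 100.0%
```

The cohort's mean effect of ~6 percentage points on prolonged abstinence
hides substantial heterogeneity (SD 7.0): the second stage shows the
standardized effects rising with age (+0.055 SD per year beyond the mean),
for men versus women, and with baseline importance of quitting — the
directions planted in the simulator's truth.  The full pipeline (both
outcomes, both follow-ups, plots, manifest) runs from the shell:

```bash
trialite run-all --seed 7 --out my_run          # reduced scale, n=400
trialite run-all --paper-scale --seed 7 --out my_run_full
trialite report --run-dir my_run
```

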