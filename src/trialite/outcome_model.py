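"""Bayesian multilevel logistic outcome model.

The linear predictor for an observed record of participant i at follow-up t
with allocation G is

    logit P(Y=1) = alpha + u_i + b_t * t + b_g * G + b_tg * t*G
                   + x_i' beta_main + G * x_i' beta_int

with participant-level adaptive intercepts u_i.  Priors:

* covariate x group interaction coefficients: Cauchy(0, tau), with one
  common scale tau given a half-normal(0, 1) hyperprior (a hierarchical
  shrinkage prior that pulls weakly supported interactions to the null);
  a per-coefficient-scale variant and a fixed Student-t(3, 0, 2.5) variant
  are available;
* all other non-intercept coefficients: Student-t(3, 0, 2.5);
* fixed intercept: standard normal;
* adaptive intercepts: normal(0, sigma_u), sigma_u ~ half-normal(0, 1),
  sampled in a non-centered parameterization.

Scale parameters are sampled on the log scale with the appropriate
Jacobian terms; posterior draws of tau and sigma_u are therefore strictly
positive by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import TrialDataset
from .design import Design, DesignSpec, build_design
from .nuts import sample_chains

__all__ = [
    "PriorConfig",
    "PosteriorDraws",
    "DiagnosticsReport",
    "BayesianOutcomeModel",
    "fit_outcome_model",
    "check_diagnostics",
]


@dataclasses.dataclass
class PriorConfig:
    """Prior hierarchy for the outcome model.

    ``interaction_prior`` is one of ``hierarchical_cauchy`` (default: common
    tau), ``hierarchical_cauchy_percoef`` (one tau per interaction), or
    ``student_t`` (fixed t(3, 0, 2.5), no hyperprior).
    """

    noninteraction_df: float = 3.0
    noninteraction_scale: float = 2.5
    intercept_scale: float = 1.0
    tau_scale: float = 1.0  # half-normal hyperprior scale for tau
    sigma_u_scale: float = 1.0  # half-normal prior scale for sigma_u
    interaction_prior: str = "hierarchical_cauchy"
    #: "centered" samples the natural interaction coefficients under the
    #: Cauchy density directly (bounded gradients, robust step-size
    #: adaptation); "mixture" uses the normal/inverse-gamma non-centered
    #: scale mixture (shallower trajectories, but its inverse-gamma wall
    #: can defeat a step size adapted away from it).
    interaction_parameterization: str = "centered"

    def validate(self):
        if min(
            self.noninteraction_scale,
            self.intercept_scale,
            self.tau_scale,
            self.sigma_u_scale,
        ) <= 0:
            raise ValueError("all prior scales must be strictly positive")
        if self.interaction_prior not in {
            "hierarchical_cauchy",
            "hierarchical_cauchy_percoef",
            "student_t",
        }:
            raise ValueError(f"unknown interaction prior {self.interaction_prior!r}")
        if self.interaction_parameterization not in {"centered", "mixture"}:
            raise ValueError(
                f"unknown parameterization {self.interaction_parameterization!r}"
            )
        return self


@dataclasses.dataclass
class PosteriorDraws:
    """Named MCMC draws, kept per chain for diagnostics.

    ``chains_array`` has shape (chains, draws_per_chain, n_params); columns
    follow ``names``: fixed-effect design columns, then ``sigma_u``, then
    ``tau`` columns (if any), then one adaptive-intercept column per
    participant (``u[<participant_id>]``, on the intercept scale).
    """

    chains_array: np.ndarray
    names: list[str]
    n_fixed: int
    seed: int
    n_warmup: int
    sampler_stats: list = dataclasses.field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.chains_array.shape[0]

    @property
    def n_draws(self) -> int:
        """Total draws S = chains x post-warmup draws per chain."""
        return self.chains_array.shape[0] * self.chains_array.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """(S, n_params) flattened draw matrix."""
        return self.chains_array.reshape(-1, self.chains_array.shape[-1])

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def fixed(self) -> np.ndarray:
        """(S, p) draws of the fixed-effect coefficients."""
        return self.matrix[:, : self.n_fixed]

    def adaptive_intercepts(self) -> np.ndarray:
        """(S, n_participants) draws of the adaptive intercepts u_i."""
        start = next(
            i for i, n in enumerate(self.names) if n.startswith("u[")
        )
        return self.matrix[:, start:]

    def summary(self) -> pd.DataFrame:
        """Median and central 95% interval per parameter."""
        mat = self.matrix
        cols = self.names
        med = np.median(mat, axis=0)
        lo, hi = np.percentile(mat, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {"parameter": cols, "median": med, "q2.5": lo, "q97.5": hi}
        )


@dataclasses.dataclass
class DiagnosticsReport:
    rhat: pd.Series
    ess: pd.Series
    flagged: pd.DataFrame  # parameter, rhat, ess, reason
    passed: bool
    rhat_threshold: float
    ess_threshold: float


def check_diagnostics(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.01,
    ess_threshold: float = 400.0,
) -> DiagnosticsReport:
    """Split R-hat and bulk effective sample size for every parameter.

    Parameters whose chains are exactly constant (zero variance) are
    flagged as degenerate rather than producing division failures.
    Requires at least two chains.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    arr = draws.chains_array
    variances = arr.var(axis=(0, 1))
    degenerate = variances == 0.0
    idata = az.from_dict(posterior={"theta": arr})
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.asarray(az.rhat(idata)["theta"])
        ess = np.asarray(az.ess(idata)["theta"])
    rhat_s = pd.Series(rhat, index=draws.names, name="rhat")
    ess_s = pd.Series(ess, index=draws.names, name="ess")
    rows = []
    for i, name in enumerate(draws.names):
        if degenerate[i]:
            rows.append((name, np.nan, np.nan, "degenerate chain"))
        elif not np.isfinite(rhat[i]) or rhat[i] > rhat_threshold:
            rows.append((name, rhat[i], ess[i], "rhat above threshold"))
        elif ess[i] < ess_threshold:
            rows.append((name, rhat[i], ess[i], "ess below threshold"))
    flagged = pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "reason"])
    return DiagnosticsReport(
        rhat=rhat_s,
        ess=ess_s,
        flagged=flagged,
        passed=flagged.empty,
        rhat_threshold=rhat_threshold,
        ess_threshold=ess_threshold,
    )


def _make_logp_grad(design: Design, priors: PriorConfig):
    """Unconstrained posterior log-density and gradient.

    Parameter layout: [beta (p), u_raw (n), log_sigma_u, log_tau (n_tau),
    w (k_inter, mixture parameterization only)].  The adaptive intercepts
    are non-centered (u = sigma_u * u_raw).

    Under the hierarchical Cauchy prior with the default ``centered``
    parameterization the interaction entries of ``beta`` are the natural
    coefficients and contribute the Cauchy(0, tau) density directly (its
    gradient is bounded, which keeps step-size adaptation stable).  Under
    ``mixture`` they hold standardized coordinates z with
    beta = tau * z * exp(w / 2), exp(w) ~ inverse-gamma(1/2, 1/2): the
    normal/inverse-gamma scale mixture whose marginal is exactly
    Cauchy(0, tau).
    """
    X = design.X
    y = design.y
    pidx = design.participant_index
    n_obs, p = X.shape
    n_part = design.n_participants
    inter = design.idx_interactions
    k_inter = inter.stop - inter.start
    percoef = priors.interaction_prior == "hierarchical_cauchy_percoef"
    hier = priors.interaction_prior in (
        "hierarchical_cauchy",
        "hierarchical_cauchy_percoef",
    )
    mixture = hier and priors.interaction_parameterization == "mixture"
    n_tau = (k_inter if percoef else 1) if hier else 0
    n_w = k_inter if mixture else 0
    dim = p + n_part + 1 + n_tau + n_w
    X_int = X[:, inter]

    # t(df, 0, s) log-density kernel and gradient factors
    df = priors.noninteraction_df
    s2df = priors.noninteraction_scale**2 * df
    t_coef = -(df + 1.0)

    nonint = np.zeros(p, bool)
    nonint[1:4] = True  # time, group, time:group
    nonint[design.idx_mains] = True

    def natural_beta(theta: np.ndarray) -> np.ndarray:
        """Fixed-effect vector on the natural scale."""
        beta = theta[:p].copy()
        if mixture:
            tau = np.exp(theta[p + n_part + 1 : p + n_part + 1 + n_tau])
            w = theta[p + n_part + 1 + n_tau :]
            beta[inter] = tau * beta[inter] * np.exp(0.5 * w)
        return beta

    def logp_grad(theta: np.ndarray):
        beta = theta[:p]
        u_raw = theta[p : p + n_part]
        log_su = theta[p + n_part]
        sigma_u = np.exp(log_su)
        grad = np.zeros_like(theta)

        if mixture:
            log_tau = theta[p + n_part + 1 : p + n_part + 1 + n_tau]
            tau = np.exp(log_tau)
            w = theta[p + n_part + 1 + n_tau :]
            sqrt_v = np.exp(0.5 * w)
            z = beta[inter]
            bi = tau * z * sqrt_v
            eta = X[:, : inter.start] @ beta[: inter.start] + X_int @ bi
        else:
            eta = X @ beta
        eta = eta + sigma_u * u_raw[pidx]
        mu = expit(eta)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())  # Bernoulli, stable
        resid = y - mu
        gbeta = X.T @ resid  # w.r.t. natural coefficients
        bc = np.bincount(pidx, weights=resid, minlength=n_part)
        grad[p : p + n_part] = sigma_u * bc - u_raw
        lp = ll - 0.5 * float(u_raw @ u_raw)
        lp += -0.5 * (sigma_u / priors.sigma_u_scale) ** 2 + log_su
        grad[p + n_part] = (
            sigma_u * float(u_raw @ bc)
            - (sigma_u / priors.sigma_u_scale) ** 2
            + 1.0
        )

        # fixed intercept ~ normal(0, intercept_scale)
        b0 = beta[0]
        lp += -0.5 * (b0 / priors.intercept_scale) ** 2
        gbeta[0] += -b0 / priors.intercept_scale**2

        # non-interaction coefficients ~ t(df, 0, scale)
        bn = beta[nonint]
        lp += 0.5 * t_coef * float(np.sum(np.log1p(bn**2 / s2df)))
        gbeta[nonint] += t_coef * bn / (s2df + bn**2)

        if mixture:
            dll_dbi = gbeta[inter]  # prior-free: interactions' prior sits in z, w
            grad[:p] = gbeta
            grad[inter] = dll_dbi * tau * sqrt_v - z  # z ~ normal(0, 1)
            # w: likelihood (dbeta/dw = beta/2) + inv-gamma(1/2,1/2) + Jacobian
            grad_w = 0.5 * dll_dbi * bi - 0.5 + 0.5 * np.exp(-w)
            grad[p + n_part + 1 + n_tau :] = grad_w
            lp += -0.5 * float(z @ z)
            lp += float(np.sum(-0.5 * w - 0.5 * np.exp(-w)))
            # tau: likelihood (dbeta/dlog_tau = beta) + half-normal + Jacobian
            dltau = dll_dbi * bi
            if percoef:
                grad[p + n_part + 1 : p + n_part + 1 + n_tau] = (
                    dltau - (tau / priors.tau_scale) ** 2 + 1.0
                )
            else:
                grad[p + n_part + 1] = (
                    float(np.sum(dltau)) - (tau[0] / priors.tau_scale) ** 2 + 1.0
                )
            lp += float(np.sum(-0.5 * (tau / priors.tau_scale) ** 2 + log_tau))
        elif hier:
            # centered: natural interaction coefficients ~ Cauchy(0, tau)
            log_tau = theta[p + n_part + 1 :]
            tau = np.exp(log_tau)
            bi = beta[inter]
            denom = tau**2 + bi**2
            lp += float(np.sum(-np.log(np.pi * tau) - np.log1p((bi / tau) ** 2)))
            gbeta[inter] += -2.0 * bi / denom
            grad[:p] = gbeta
            # d/d log_tau: Cauchy scale term + half-normal hyperprior + Jacobian
            dltau = (bi**2 - tau**2) / denom
            if percoef:
                grad[p + n_part + 1 :] = dltau - (tau / priors.tau_scale) ** 2 + 1.0
            else:
                grad[p + n_part + 1] = (
                    float(np.sum(dltau)) - (tau[0] / priors.tau_scale) ** 2 + 1.0
                )
            lp += float(np.sum(-0.5 * (tau / priors.tau_scale) ** 2 + log_tau))
        else:
            bi = beta[inter]
            lp += 0.5 * t_coef * float(np.sum(np.log1p(bi**2 / s2df)))
            gbeta[inter] += t_coef * bi / (s2df + bi**2)
            grad[:p] = gbeta
        return lp, grad

    return logp_grad, dim, n_tau, percoef, natural_beta


def fit_outcome_model(
    dataset: TrialDataset,
    outcome: str,
    spec: DesignSpec | None = None,
    priors: PriorConfig | None = None,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> tuple[PosteriorDraws, Design]:
    """Fit the multilevel logistic model for one outcome by NUTS.

    Both follow-ups enter one fit through the time and time x group terms.
    Returns named posterior draws (with tau and sigma_u on their natural
    scales and adaptive intercepts u_i = sigma_u * u_raw_i) plus the
    realized design.
    """
    priors = (priors or PriorConfig()).validate()
    design = build_design(dataset, outcome, spec)
    if design.X.size == 0:
        raise ValueError("empty design")
    for arm in (0, 1):
        if not np.any(design.X[:, design.idx_group] == arm):
            raise ValueError(f"no observed outcomes in arm {arm}")
    logp_grad, dim, n_tau, percoef, natural_beta = _make_logp_grad(design, priors)
    p = design.X.shape[1]
    n_part = design.n_participants

    def init(rng):
        x0 = np.zeros(dim)
        x0[:p] = rng.uniform(-0.2, 0.2, p)
        x0[p : p + n_part] = rng.uniform(-0.5, 0.5, n_part)
        x0[p + n_part : p + n_part + 1 + n_tau] = rng.uniform(-1.0, -0.5, 1 + n_tau)
        return x0

    # Fisher-information guess for the initial inverse mass: per-unit
    # covariates (age in years, cigarettes per week) give wildly different
    # coefficient scales, and unit masses would cripple early warmup.
    curv = 0.25 * (design.X**2).sum(axis=0) + 1.0 / (
        priors.noninteraction_df * priors.noninteraction_scale**2
    )
    curv[0] += 1.0 / priors.intercept_scale**2
    inv0 = np.ones(dim)
    inv0[:p] = 1.0 / curv
    mixture = n_tau > 0 and priors.interaction_parameterization == "mixture"
    if mixture:
        inv0[design.idx_interactions] = 1.0  # standardized z coordinates
    nobs = np.bincount(design.participant_index, minlength=n_part)
    inv0[p : p + n_part] = 1.0 / (0.25 * nobs + 1.0)

    arr, stats = sample_chains(
        logp_grad,
        init,
        dim,
        chains,
        warmup,
        draws,
        seed=seed,
        target_accept=target_accept,
        max_treedepth=max_treedepth,
        init_inv_mass=inv0,
    )
    # repackage on natural scales: beta_int, sigma_u, tau, u_i = sigma_u * u_raw_i
    beta_nat = arr[:, :, :p].copy()
    if mixture:
        tau_d = np.exp(arr[:, :, p + n_part + 1 : p + n_part + 1 + n_tau])
        w_d = arr[:, :, p + n_part + 1 + n_tau :]
        beta_nat[:, :, design.idx_interactions] = (
            tau_d * beta_nat[:, :, design.idx_interactions] * np.exp(0.5 * w_d)
        )
    sigma_u = np.exp(arr[:, :, p + n_part])
    u = arr[:, :, p : p + n_part] * sigma_u[:, :, None]
    blocks = [beta_nat, sigma_u[:, :, None]]
    names = list(design.columns) + ["sigma_u"]
    if n_tau:
        tau = np.exp(arr[:, :, p + n_part + 1 : p + n_part + 1 + n_tau])
        blocks.append(tau)
        if percoef:
            inter_names = design.columns[design.idx_interactions]
            names += [f"tau[{c}]" for c in inter_names]
        else:
            names += ["tau"]
    blocks.append(u)
    names += [f"u[{pid}]" for pid in design.participant_ids]
    packed = np.concatenate(blocks, axis=2)
    post = PosteriorDraws(
        chains_array=packed,
        names=names,
        n_fixed=p,
        seed=seed,
        n_warmup=warmup,
        sampler_stats=stats,
    )
    return post, design


class BayesianOutcomeModel:
    """Multilevel Bayesian logistic outcome model, estimator style.

    Parameters
    ----------
    covariates : list of baseline covariate names (default: all).
    priors : PriorConfig, the shrinkage-prior hierarchy.
    chains, warmup, draws, seed, target_accept, max_treedepth : sampler
        settings (defaults: 4 chains x 1000 warmup + 1000 draws).
    counterfactual : adaptive-intercept convention for counterfactual
        prediction: ``"zero"`` (population-typical participant, default),
        ``"draws"`` (each participant's posterior intercept draws), or
        ``"marginal"`` (Gauss-Hermite average over the intercept
        distribution).

    Fitted attributes: ``draws_``, ``design_``, ``diagnostics_``.
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        priors: PriorConfig | None = None,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        seed: int = 0,
        target_accept: float = 0.8,
        max_treedepth: int = 10,
        counterfactual: str = "zero",
    ):
        self.covariates = covariates
        self.priors = priors
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.counterfactual = counterfactual

    _param_names = (
        "covariates",
        "priors",
        "chains",
        "warmup",
        "draws",
        "seed",
        "target_accept",
        "max_treedepth",
        "counterfactual",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "BayesianOutcomeModel":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, dataset: TrialDataset, outcome: str) -> "BayesianOutcomeModel":
        if self.counterfactual not in ("zero", "draws", "marginal"):
            raise ValueError(f"unknown counterfactual convention {self.counterfactual!r}")
        spec = DesignSpec(covariates=list(self.covariates)) if self.covariates else None
        self.outcome_ = outcome
        self.draws_, self.design_ = fit_outcome_model(
            dataset,
            outcome,
            spec=spec,
            priors=self.priors,
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            seed=self.seed,
            target_accept=self.target_accept,
            max_treedepth=self.max_treedepth,
        )
        if self.chains >= 2:
            self.diagnostics_ = check_diagnostics(self.draws_)
        else:
            self.diagnostics_ = None
        return self

    def predict_proba(
        self, baseline: pd.DataFrame, arm: int, timepoint: str
    ) -> np.ndarray:
        """Per-draw counterfactual outcome probabilities, shape (S, n).

        The adaptive intercept enters per ``self.counterfactual``; under the
        default ``"zero"`` convention predictions are functions of the
        baseline covariates alone.
        """
        if not hasattr(self, "draws_"):
            raise ValueError("model is not fitted")
        Xp = self.design_.encode_profiles(baseline, arm, timepoint)
        eta = self.draws_.fixed() @ Xp.T  # (S, n)
        if self.counterfactual == "zero":
            return expit(eta)
        if self.counterfactual == "draws":
            ids = baseline["participant_id"].tolist()
            known = set(self.design_.participant_ids)
            missing = [i for i in ids if i not in known]
            if missing:
                raise ValueError(
                    f"no posterior intercept draws for participants {missing[:3]}"
                )
            u = self.draws_.adaptive_intercepts()
            pos = {pid: j for j, pid in enumerate(self.design_.participant_ids)}
            cols = [pos[i] for i in ids]
            return expit(eta + u[:, cols])
        # marginal: average over u ~ normal(0, sigma_u) by Gauss-Hermite
        nodes, weights = np.polynomial.hermite_e.hermegauss(16)
        weights = weights / weights.sum()
        sigma = self.draws_.column("sigma_u")[:, None]
        out = np.zeros_like(eta)
        for z, w in zip(nodes, weights):
            out += w * expit(eta + sigma * z)
        return out
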