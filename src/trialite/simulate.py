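"""Synthetic two-arm smoking-cessation trials with known ground truth.

The generator emulates the structure of a pragmatic SMS-support cessation
trial: ~1000 participants, 1:1 stratified permuted-block randomization
(blocks of 2 and 4, stratified on planned elective surgery), two binary
abstinence outcomes (prolonged / point prevalence) at 3- and 6-month
follow-ups, participant-level random intercepts linking the repeated
measurements, heterogeneous treatment effects driven by baseline-covariate
x group interactions on the logit scale, and follow-up nonresponse that is
arm- and age-dependent (older participants respond more at 6 months).

Marginal covariate distributions are calibrated so that large samples hit
the configured means/SDs and category proportions exactly (moment-matched
truncated normals and scaled Betas; a quadrature-calibrated smoking-onset
construction keeps years_smoking < age row-wise while matching its marginal
moments).  The joint distribution is an independence copula by default,
with an optional Gaussian-copula correlation hook.
"""

from __future__ import annotations

import dataclasses
import functools
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import expit

from . import design as _design
from .dataset import (
    CATEGORICAL_LEVELS,
    FLAG_COLUMNS,
    OUTCOMES,
    TIMEPOINTS,
    TrialDataset,
)

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "OutcomeDGP",
    "MissingnessDGP",
    "TrueDGP",
    "SimTruth",
    "TrialSimulator",
    "generate_baseline",
    "randomize",
    "true_ite",
    "generate_outcomes",
    "apply_missingness",
    "simulate_trial",
    "nexit_like_dgp",
    "null_dgp",
    "expected_response_rates",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# moment-matched marginal families
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=None)
def _truncnorm_params(mean: float, sd: float, lower: float, upper: float):
    """Underlying normal (loc, scale) whose [lower, upper] truncation has the
    requested mean and SD."""

    def resid(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        a, b = (lower - loc) / scale, (upper - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or np.max(np.abs(resid(sol.x))) > 1e-6:
        raise ConfigError(
            f"no truncated normal on [{lower}, {upper}] attains "
            f"mean {mean}, sd {sd}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _beta_params(mean: float, sd: float, lower: float, upper: float):
    """Moment-matched scaled Beta on [lower, upper]."""
    span = upper - lower
    m = (mean - lower) / span
    v = (sd / span) ** 2
    if not 0 < m < 1 or v >= m * (1 - m):
        raise ConfigError(
            f"no Beta on [{lower}, {upper}] attains mean {mean}, sd {sd}"
        )
    nu = m * (1 - m) / v - 1
    return m * nu, (1 - m) * nu


@functools.lru_cache(maxsize=None)
def _lognormal_count_params(mean: float, sd: float):
    """Lognormal (mu, sigma) such that the *rounded* variate has the
    requested mean and SD (rounding bias solved for, not ignored)."""
    cv2 = (sd / mean) ** 2
    sig0 = np.sqrt(np.log1p(cv2))
    mu0 = np.log(mean) - 0.5 * sig0**2

    def rounded_moments(mu, sig):
        kmax = int(np.ceil(stats.lognorm.ppf(1 - 1e-9, sig, scale=np.exp(mu)))) + 1
        k = np.arange(kmax + 1)
        upper_cdf = stats.lognorm.cdf(k + 0.5, sig, scale=np.exp(mu))
        lower_cdf = stats.lognorm.cdf(np.maximum(k - 0.5, 0.0), sig, scale=np.exp(mu))
        p = upper_cdf - lower_cdf
        m1 = float(np.sum(k * p))
        m2 = float(np.sum(k**2 * p))
        return m1, np.sqrt(max(m2 - m1**2, 0.0))

    def resid(p):
        m1, s1 = rounded_moments(p[0], np.exp(p[1]))
        return [m1 - mean, s1 - sd]

    sol = optimize.root(resid, x0=[mu0, np.log(sig0)], method="hybr")
    if not sol.success or np.max(np.abs(resid(sol.x))) > 1e-6:
        raise ConfigError(f"no rounded lognormal attains mean {mean}, sd {sd}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


@functools.lru_cache(maxsize=None)
def _start_age_params(
    age_mean: float,
    age_sd: float,
    age_lower: float,
    age_upper: float,
    years_mean: float,
    years_sd: float,
    start_lower: float,
):
    """Smoking-onset-age distribution for the age-linked years_smoking family.

    years_smoking = max(age - start_age, 0) with start_age ~ truncated normal
    on [start_lower, inf).  The onset (loc, scale) are solved by quadrature
    so the *marginal* of years_smoking attains the requested mean and SD.
    """
    loc_a, sc_a = _truncnorm_params(age_mean, age_sd, age_lower, age_upper)
    aa, ab = (age_lower - loc_a) / sc_a, (age_upper - loc_a) / sc_a
    nodes, weights = np.polynomial.legendre.leggauss(200)
    a = 0.5 * (age_upper - age_lower) * nodes + 0.5 * (age_upper + age_lower)
    w = weights * 0.5 * (age_upper - age_lower) * stats.truncnorm.pdf(
        a, aa, ab, loc=loc_a, scale=sc_a
    )

    def clipped_moments(mu_s, sc_s):
        # closed-form partial moments of the onset truncnorm on [start_lower, a]
        alpha = (start_lower - mu_s) / sc_s
        Z = stats.norm.sf(alpha)
        b = (a - mu_s) / sc_s
        P0 = stats.norm.cdf(b) - stats.norm.cdf(alpha)
        dphi = stats.norm.pdf(alpha) - stats.norm.pdf(b)
        P1 = mu_s * P0 + sc_s * dphi
        P2 = (
            mu_s**2 * P0
            + 2 * mu_s * sc_s * dphi
            + sc_s**2 * (P0 - b * stats.norm.pdf(b) + alpha * stats.norm.pdf(alpha))
        )
        e1 = (a * P0 - P1) / Z  # E[max(a - s, 0) | age = a]
        e2 = (a**2 * P0 - 2 * a * P1 + P2) / Z
        m1 = float(np.sum(w * e1))
        m2 = float(np.sum(w * e2))
        return m1, np.sqrt(max(m2 - m1**2, 0.0))

    def resid(p):
        m1, s1 = clipped_moments(p[0], np.exp(p[1]))
        return [m1 - years_mean, s1 - years_sd]

    sol = optimize.root(resid, x0=[age_mean - years_mean, np.log(5.0)], method="hybr")
    if not sol.success or np.max(np.abs(resid(sol.x))) > 1e-4:
        raise ConfigError(
            f"no onset-age distribution attains years_smoking mean "
            f"{years_mean}, sd {years_sd} given the age marginal"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_yaml_path() -> Path:
    return Path(__file__).parent / "data" / "nexit_default.yaml"


@dataclasses.dataclass
class GeneratorConfig:
    """Synthetic-trial generator settings.

    ``marginals`` maps each baseline column to a family spec:

    - ``{kind: categorical, levels: [...], probs: [...]}``
    - ``{kind: flag, prob: p}``
    - ``{kind: truncnorm, mean, sd, lower, upper}`` (moment-matched)
    - ``{kind: beta, mean, sd, lower, upper}`` (moment-matched, for bounded
      0-10 scores whose mean sits near a bound)
    - ``{kind: lognormal_count, mean, sd}`` (rounded to integer counts)
    - ``{kind: age_linked, mean, sd, start_lower}`` (years_smoking; keeps
      years_smoking < age row-wise)

    ``correlation`` optionally lists Gaussian-copula correlations as
    ``[[col_a, col_b, rho], ...]``; default is independence.
    """

    n: int = 1012
    marginals: dict = dataclasses.field(default_factory=dict)
    correlation: list = dataclasses.field(default_factory=list)
    block_sizes: list = dataclasses.field(default_factory=lambda: [2, 4])
    strata: str = "elective_surgery"
    seed: int = 0

    @classmethod
    def default(cls) -> "GeneratorConfig":
        return cls.from_yaml(_default_yaml_path())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> "GeneratorConfig":
        if self.n < 0:
            raise ConfigError(f"n must be non-negative, got {self.n}")
        for size in self.block_sizes:
            if size <= 0 or size % 2:
                raise ConfigError(
                    f"block sizes must be positive and even for 1:1 "
                    f"allocation, got {size}"
                )
        for col, spec in self.marginals.items():
            kind = spec.get("kind")
            if kind == "categorical":
                probs = np.asarray(spec["probs"], float)
                if (probs < 0).any() or (probs > 1).any():
                    raise ConfigError(f"{col}: proportions must lie in [0, 1]")
                if abs(probs.sum() - 1.0) > 1e-6:
                    raise ConfigError(
                        f"{col}: proportions sum to {probs.sum():.6f}, not 1"
                    )
                if list(spec["levels"]) != CATEGORICAL_LEVELS.get(col, list(spec["levels"])):
                    raise ConfigError(f"{col}: levels must be {CATEGORICAL_LEVELS[col]}")
            elif kind == "flag":
                if not 0 <= spec["prob"] <= 1:
                    raise ConfigError(f"{col}: prob must lie in [0, 1]")
            elif kind not in {"truncnorm", "beta", "lognormal_count", "age_linked"}:
                raise ConfigError(f"{col}: unknown marginal kind {kind!r}")
        return self


# ---------------------------------------------------------------------------
# baseline generation
# ---------------------------------------------------------------------------


def _copula_uniforms(config: GeneratorConfig, columns: list[str], rng) -> pd.DataFrame:
    """One uniform per participant x column, from a Gaussian copula."""
    k = len(columns)
    corr = np.eye(k)
    pos = {c: i for i, c in enumerate(columns)}
    for entry in config.correlation:
        a, b, rho = entry
        if a not in pos or b not in pos:
            raise ConfigError(f"correlation names unknown column: {entry}")
        corr[pos[a], pos[b]] = corr[pos[b], pos[a]] = float(rho)
    if config.correlation:
        # nearest-PD guard for a user-supplied pairwise spec
        lo = np.linalg.eigvalsh(corr)[0]
        if lo < 1e-8:
            corr += (1e-8 - lo) * np.eye(k)
    z = rng.standard_normal((config.n, k)) @ np.linalg.cholesky(corr).T
    return pd.DataFrame(stats.norm.cdf(z), columns=columns)


def generate_baseline(
    config: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw a baseline table of ``config.n`` participants.

    Deterministic given the seed (``config.seed`` unless overridden).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    marg = config.marginals
    columns = list(marg)
    # the onset-age construction needs an extra uniform stream
    u = _copula_uniforms(config, columns + ["_start_age"], rng)

    out: dict[str, np.ndarray | list] = {}
    age_spec = marg.get("age")
    for col in columns:
        spec = marg[col]
        kind = spec["kind"]
        uu = u[col].to_numpy()
        if kind == "categorical":
            cum = np.cumsum(spec["probs"])
            idx = np.searchsorted(cum, uu, side="right").clip(0, len(cum) - 1)
            out[col] = [spec["levels"][i] for i in idx]
        elif kind == "flag":
            out[col] = uu < spec["prob"]
        elif kind == "truncnorm":
            loc, sc = _truncnorm_params(
                spec["mean"], spec["sd"], spec["lower"], spec["upper"]
            )
            a, b = (spec["lower"] - loc) / sc, (spec["upper"] - loc) / sc
            out[col] = stats.truncnorm.ppf(uu, a, b, loc=loc, scale=sc)
        elif kind == "beta":
            al, be = _beta_params(spec["mean"], spec["sd"], spec["lower"], spec["upper"])
            span = spec["upper"] - spec["lower"]
            out[col] = spec["lower"] + span * stats.beta.ppf(uu, al, be)
        elif kind == "lognormal_count":
            mu, sig = _lognormal_count_params(spec["mean"], spec["sd"])
            out[col] = np.round(stats.lognorm.ppf(uu, sig, scale=np.exp(mu)))
        elif kind == "age_linked":
            if age_spec is None or age_spec["kind"] != "truncnorm":
                raise ConfigError("age_linked marginal requires a truncnorm 'age'")
            mu_s, sc_s = _start_age_params(
                age_spec["mean"],
                age_spec["sd"],
                age_spec["lower"],
                age_spec["upper"],
                spec["mean"],
                spec["sd"],
                spec.get("start_lower", 10.0),
            )
            lo = spec.get("start_lower", 10.0)
            start = stats.truncnorm.ppf(
                u["_start_age"].to_numpy(),
                (lo - mu_s) / sc_s,
                np.inf,
                loc=mu_s,
                scale=sc_s,
            )
            out[col] = ("_age_linked", start)  # resolved after age is drawn

    # resolve age-linked columns now that age exists
    for col, val in list(out.items()):
        if isinstance(val, tuple) and val[0] == "_age_linked":
            age = np.asarray(out["age"], float)
            out[col] = np.maximum(age - val[1], 0.0)

    table = pd.DataFrame(out)
    table.insert(
        0,
        "participant_id",
        [f"P{i:06d}" for i in range(config.n)],
    )
    return table


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------


def randomize(
    baseline: pd.DataFrame, config: GeneratorConfig, seed: int | None = None
) -> pd.Series:
    """1:1 stratified permuted-block allocation.

    Within each stratum, block lengths are drawn uniformly from
    ``config.block_sizes`` and each block is a random permutation of equal
    numbers of 0s and 1s; a truncated final block bounds the per-stratum
    imbalance by the largest block size.
    """
    if config.strata not in baseline.columns:
        raise ConfigError(f"stratification covariate {config.strata!r} not in baseline")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    alloc = pd.Series(0, index=baseline["participant_id"], dtype=int, name="group")
    for _, sub in baseline.groupby(config.strata, sort=True):
        ids = sub["participant_id"].tolist()
        seq: list[int] = []
        while len(seq) < len(ids):
            size = int(rng.choice(config.block_sizes))
            block = np.repeat([0, 1], size // 2)
            rng.shuffle(block)
            seq.extend(block.tolist())
        alloc.loc[ids] = seq[: len(ids)]
    return alloc


# ---------------------------------------------------------------------------
# data-generating process
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class OutcomeDGP:
    """Logit-scale truth for one outcome.

    ``main`` and ``interaction`` are keyed by *design column* names (e.g.
    ``age``, ``man``, ``snus_none``); interactions act only under G=1.
    """

    intercept: float = 0.0
    time: float = 0.0
    group: float = 0.0
    time_group: float = 0.0
    main: dict = dataclasses.field(default_factory=dict)
    interaction: dict = dataclasses.field(default_factory=dict)
    sigma_u: float = 1.0

    def validate(self):
        vals = [self.intercept, self.time, self.group, self.time_group]
        vals += list(self.main.values()) + list(self.interaction.values())
        if not np.all(np.isfinite(vals)):
            raise ConfigError("all DGP coefficients must be finite")
        if self.sigma_u < 0:
            raise ConfigError("adaptive-intercept SD must be >= 0")
        return self


@dataclasses.dataclass
class MissingnessDGP:
    """Logistic follow-up-response model per timepoint: intercept + arm*G +
    age*(age - age_center).  The default gives ~69/66% response at 3 months
    (control/intervention), ~64% at 6 months, with a positive 6-month age
    coefficient (older participants more likely to respond)."""

    intercept: dict = dataclasses.field(
        default_factory=lambda: {"3mo": 0.80, "6mo": 0.62}
    )
    arm: dict = dataclasses.field(default_factory=lambda: {"3mo": -0.14, "6mo": 0.0})
    age: dict = dataclasses.field(default_factory=lambda: {"3mo": 0.0, "6mo": 0.02})


@dataclasses.dataclass
class TrueDGP:
    """Complete synthetic-trial truth: one OutcomeDGP per outcome, the
    follow-up-response model, and the covariate centering constants that the
    logit-scale coefficients refer to."""

    outcomes: dict = dataclasses.field(default_factory=dict)
    missingness: MissingnessDGP = dataclasses.field(default_factory=MissingnessDGP)
    centers: dict = dataclasses.field(
        default_factory=lambda: {
            "age": 45.4,
            "years_smoking": 25.3,
            "cigarettes_per_week": 101.0,
            "fagerstrom": 5.0,
            "quit_attempts": 7.2,
            "importance": 9.4,
            "confidence": 6.2,
            "knowhow": 5.5,
        }
    )
    share_intercept: bool = False

    def validate(self):
        for odgp in self.outcomes.values():
            odgp.validate()
        return self


def nexit_like_dgp() -> TrueDGP:
    """Default truth resembling the trial's reported effect sizes: control
    prolonged abstinence ~8%, group log-odds ~0.75 (mean individual effect
    ~7 percentage points), weaker point-prevalence effect (~4 points), age,
    importance and smoking-intensity interactions, unit random-intercept SD."""
    return TrueDGP(
        outcomes={
            "prolonged": OutcomeDGP(
                intercept=-2.45,
                time=-0.2,
                group=0.75,
                time_group=0.1,
                main={"age": 0.01, "man": -0.2, "importance": 0.15,
                      "confidence": 0.10, "cigarettes_per_week": -0.003},
                interaction={"age": 0.025, "man": 0.3, "importance": 0.25,
                             "cigarettes_per_week": -0.004},
                sigma_u=1.0,
            ),
            "point_prevalence": OutcomeDGP(
                intercept=-2.0,
                time=-0.1,
                group=0.35,
                time_group=-0.05,
                main={"age": 0.01, "confidence": 0.10,
                      "cigarettes_per_week": -0.003},
                interaction={"age": 0.02, "confidence": 0.08,
                             "cigarettes_per_week": -0.003},
                sigma_u=1.0,
            ),
        }
    )


def null_dgp(sigma_u: float = 1.0, intercept: float = -2.2) -> TrueDGP:
    """All treatment-side coefficients zero for both outcomes."""
    return TrueDGP(
        outcomes={
            name: OutcomeDGP(intercept=intercept, time=-0.1, sigma_u=sigma_u)
            for name in OUTCOMES
        }
    )


def _linpred(
    dgp: TrueDGP,
    odgp: OutcomeDGP,
    baseline: pd.DataFrame,
    group: np.ndarray,
    timepoint: str,
) -> np.ndarray:
    covs = [c for c in _design.ALL_COVARIATES if c in baseline.columns]
    mains, names = _design.encode_mains(baseline, covs, dgp.centers)
    lookup = dict(zip(names, mains.T))
    for key in list(odgp.main) + list(odgp.interaction):
        if key not in lookup:
            raise ConfigError(f"DGP references unknown design column {key!r}")
    t = float(timepoint == "6mo")
    eta = np.full(len(baseline), odgp.intercept + odgp.time * t, dtype=float)
    eta += (odgp.group + odgp.time_group * t) * group
    for key, coef in odgp.main.items():
        eta += coef * lookup[key]
    for key, coef in odgp.interaction.items():
        eta += coef * lookup[key] * group
    return eta


def true_ite(
    dgp: TrueDGP,
    profiles: pd.DataFrame,
    timepoint: str,
    outcome: str,
) -> np.ndarray:
    """Closed-form individualized effect delta(x) = P(Y|G=1,x) - P(Y|G=0,x),
    with the adaptive intercept at its center (0)."""
    dgp.validate()
    odgp = dgp.outcomes[outcome]
    ones = np.ones(len(profiles))
    zeros = np.zeros(len(profiles))
    return expit(_linpred(dgp, odgp, profiles, ones, timepoint)) - expit(
        _linpred(dgp, odgp, profiles, zeros, timepoint)
    )


@dataclasses.dataclass
class SimTruth:
    """Ground truth attached to a simulated trial: the DGP plus the
    closed-form per-participant effects."""

    dgp: TrueDGP
    deltas: pd.DataFrame  # participant_id, outcome, timepoint, delta

    def delta(self, outcome: str, timepoint: str) -> pd.Series:
        sub = self.deltas[
            (self.deltas["outcome"] == outcome)
            & (self.deltas["timepoint"] == timepoint)
        ]
        return sub.set_index("participant_id")["delta"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dgp": {
                "outcomes": {
                    k: dataclasses.asdict(v) for k, v in self.dgp.outcomes.items()
                },
                "missingness": dataclasses.asdict(self.dgp.missingness),
                "centers": self.dgp.centers,
                "share_intercept": self.dgp.share_intercept,
            },
            "deltas": self.deltas.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        raw = json.loads(Path(path).read_text())
        dgp = TrueDGP(
            outcomes={
                k: OutcomeDGP(**v) for k, v in raw["dgp"]["outcomes"].items()
            },
            missingness=MissingnessDGP(**raw["dgp"]["missingness"]),
            centers=raw["dgp"]["centers"],
            share_intercept=raw["dgp"]["share_intercept"],
        )
        return cls(dgp=dgp, deltas=pd.DataFrame(raw["deltas"]))


def generate_outcomes(
    baseline: pd.DataFrame,
    allocation: pd.Series,
    dgp: TrueDGP,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw complete (pre-missingness) outcome records.

    One adaptive intercept is drawn per participant (per outcome, or shared
    across outcomes when ``dgp.share_intercept``) and reused at both
    timepoints; outcomes are Bernoulli draws from the logit model.
    """
    dgp.validate()
    ids = baseline["participant_id"]
    if not set(ids) <= set(allocation.index):
        raise ConfigError("allocation does not cover all participants")
    rng = np.random.default_rng(seed)
    g = allocation.loc[ids].to_numpy(float)
    n = len(baseline)

    records = []
    truths = []
    u_shared = rng.standard_normal(n)
    for outcome in dgp.outcomes:
        odgp = dgp.outcomes[outcome]
        u = (u_shared if dgp.share_intercept else rng.standard_normal(n)) * odgp.sigma_u
        for tp in TIMEPOINTS:
            eta = _linpred(dgp, odgp, baseline, g, tp) + u
            y = (rng.random(n) < expit(eta)).astype(float)
            records.append(
                pd.DataFrame(
                    {
                        "participant_id": ids,
                        "timepoint": tp,
                        "outcome": outcome,
                        "value": y,
                    }
                )
            )
            truths.append(
                pd.DataFrame(
                    {
                        "participant_id": ids,
                        "outcome": outcome,
                        "timepoint": tp,
                        "delta": true_ite(dgp, baseline, tp, outcome),
                    }
                )
            )
    outcomes = pd.concat(records, ignore_index=True)
    truth = SimTruth(dgp=dgp, deltas=pd.concat(truths, ignore_index=True))
    return outcomes, truth


def _response_logit(
    dgp: TrueDGP, baseline: pd.DataFrame, group: np.ndarray, tp: str
) -> np.ndarray:
    m = dgp.missingness
    age_c = baseline["age"].to_numpy(float) - dgp.centers.get("age", 0.0)
    return m.intercept[tp] + m.arm[tp] * group + m.age[tp] * age_c


def expected_response_rates(
    dgp: TrueDGP, baseline: pd.DataFrame, allocation: pd.Series
) -> dict:
    """Model-implied mean follow-up-response probability per timepoint x arm."""
    g = allocation.loc[baseline["participant_id"]].to_numpy(float)
    out = {}
    for tp in TIMEPOINTS:
        p = expit(_response_logit(dgp, baseline, g, tp))
        out[tp] = {arm: float(p[g == arm].mean()) for arm in (0, 1)}
    return out


def apply_missingness(
    outcomes: pd.DataFrame,
    baseline: pd.DataFrame,
    allocation: pd.Series,
    dgp: TrueDGP,
    seed: int = 0,
) -> pd.DataFrame:
    """Blank both outcomes at every participant x timepoint whose follow-up
    response indicator (logistic in arm and age) comes up 0."""
    rng = np.random.default_rng(seed)
    ids = baseline["participant_id"]
    g = allocation.loc[ids].to_numpy(float)
    out = outcomes.copy()
    for tp in TIMEPOINTS:
        p = expit(_response_logit(dgp, baseline, g, tp))
        responded = rng.random(len(ids)) < p
        missing_ids = set(ids[~responded])
        mask = (out["timepoint"] == tp) & out["participant_id"].isin(missing_ids)
        out.loc[mask, "value"] = np.nan
    return out


def simulate_trial(
    config: GeneratorConfig | None = None,
    dgp: TrueDGP | None = None,
    seed: int | None = None,
    missingness: bool = True,
) -> tuple[TrialDataset, SimTruth]:
    """Generate a complete trial: baseline -> randomize -> outcomes ->
    missingness.  Returns the dataset and its ground truth."""
    config = config or GeneratorConfig.default()
    dgp = dgp or nexit_like_dgp()
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed).generate_state(4)
    baseline = generate_baseline(config, seed=int(ss[0]))
    alloc = randomize(baseline, config, seed=int(ss[1]))
    outcomes, truth = generate_outcomes(baseline, alloc, dgp, seed=int(ss[2]))
    if missingness:
        outcomes = apply_missingness(outcomes, baseline, alloc, dgp, seed=int(ss[3]))
    ds = TrialDataset(baseline=baseline, allocation=alloc, outcomes=outcomes)
    if config.n:
        ds.validate()
    return ds, truth


class TrialSimulator:
    """Estimator-style front end over the functional generator.

    Parameters mirror :func:`simulate_trial`; ``sample(seed)`` draws a trial
    and stores it on ``dataset_`` / ``truth_``.
    """

    def __init__(
        self,
        config: GeneratorConfig | None = None,
        dgp: TrueDGP | None = None,
        missingness: bool = True,
    ):
        self.config = config
        self.dgp = dgp
        self.missingness = missingness

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "dgp": self.dgp, "missingness": self.missingness}

    def set_params(self, **params) -> "TrialSimulator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def sample(self, seed: int | None = None) -> TrialDataset:
        self.dataset_, self.truth_ = simulate_trial(
            self.config, self.dgp, seed=seed, missingness=self.missingness
        )
        return self.dataset_
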