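"""Second-stage regressions of standardized individualized effects.

The per-participant delta point estimates are standardized (mean 0, SD 1)
and regressed on baseline factors with a Bayesian normal-likelihood linear
model under Student-t(3, 0, 2.5) coefficient priors.  Each term is reported
as its posterior median, a 95% compatibility interval (2.5/97.5
percentiles), and Prob — the percentage of posterior mass on the median's
side of zero.  An interaction variant adds the product of two covariates'
codings to their main effects (e.g. man x importance).

Posterior uncertainty in delta is deliberately not propagated: the response
is the standardized *median* point estimate, a known limitation of the
two-stage approach.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .design import DegenerateDesignError, encode_mains
from .nuts import sample_chains

__all__ = [
    "AssociationEstimate",
    "BayesianLinearRegression",
    "standardize_effects",
    "fit_association",
    "fit_interaction",
    "compute_prob",
    "credible_interval",
    "association_table",
]


def standardize_effects(values) -> np.ndarray:
    """Center and scale to mean 0, SD 1 (sample SD, n-1 denominator)."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("standardization needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize values with zero spread")
    return (x - x.mean()) / sd


def compute_prob(samples) -> float:
    """Percentage of posterior mass on the same side of zero as the median.

    Exact zeros count toward neither side.  Values near 50 mean the sign is
    undetermined; values near 100 mean a near-certain direction.
    """
    s = np.asarray(samples, float)
    if s.size == 0:
        raise ValueError("empty posterior sample")
    m = np.median(s)
    if m >= 0:
        return 100.0 * float(np.mean(s > 0))
    return 100.0 * float(np.mean(s < 0))


def credible_interval(samples, level: float = 95.0) -> tuple[float, float]:
    """Equal-tailed interval from empirical percentiles (linear
    interpolation convention)."""
    s = np.asarray(samples, float)
    if s.size == 0:
        raise ValueError("empty posterior sample")
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(s, [half, 100.0 - half])
    return float(lo), float(hi)


@dataclasses.dataclass
class AssociationEstimate:
    """One term of a second-stage model, Tables-style."""

    term: str
    median: float
    lower: float
    upper: float
    prob: float  # percentage in [50, 100] up to tie effects

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class BayesianLinearRegression:
    """Normal-likelihood linear regression with Student-t coefficient priors.

    Priors: every coefficient (intercept included) ~ t(df, 0, scale); the
    residual SD has a half-t(3, 0, scale) prior and is sampled on the log
    scale.  ``prior_scale_multiplier`` inflates all coefficient prior
    scales (set it very large to approximate flat-prior least squares).

    Fitted attributes: ``coef_draws_`` (S, p), ``sigma_draws_`` (S,),
    ``columns_``, ``estimates_`` (list of AssociationEstimate, intercept
    excluded).
    """

    def __init__(
        self,
        prior_df: float = 3.0,
        prior_scale: float = 2.5,
        prior_scale_multiplier: float = 1.0,
        sigma_scale: float = 2.5,
        chains: int = 2,
        warmup: int = 500,
        draws: int = 500,
        seed: int = 0,
        target_accept: float = 0.9,
    ):
        self.prior_df = prior_df
        self.prior_scale = prior_scale
        self.prior_scale_multiplier = prior_scale_multiplier
        self.sigma_scale = sigma_scale
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.target_accept = target_accept

    _param_names = (
        "prior_df",
        "prior_scale",
        "prior_scale_multiplier",
        "sigma_scale",
        "chains",
        "warmup",
        "draws",
        "seed",
        "target_accept",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "BayesianLinearRegression":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray, columns: list[str] | None = None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        if columns is None:
            columns = [f"x{j}" for j in range(p)]
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise DegenerateDesignError(
                f"design is rank-deficient (rank {rank} < {p} columns)"
            )
        scale = self.prior_scale * self.prior_scale_multiplier
        s2df = scale**2 * self.prior_df
        t_coef = -(self.prior_df + 1.0)
        sig_s2df = self.sigma_scale**2 * 3.0
        XtX = X.T @ X
        Xty = X.T @ y
        yty = float(y @ y)

        def logp_grad(theta):
            beta = theta[:p]
            log_s = theta[p]
            sig = np.exp(log_s)
            inv_v = 1.0 / sig**2
            Xb = XtX @ beta
            # Gaussian log-likelihood via sufficient statistics
            ssr = yty - 2.0 * float(beta @ Xty) + float(beta @ Xb)
            lp = -n * log_s - 0.5 * inv_v * ssr
            grad = np.empty_like(theta)
            grad[:p] = inv_v * (Xty - Xb)
            grad[p] = -n + inv_v * ssr
            # t priors on coefficients
            lp += 0.5 * t_coef * float(np.sum(np.log1p(beta**2 / s2df)))
            grad[:p] += t_coef * beta / (s2df + beta**2)
            # half-t(3) prior on sigma + log Jacobian
            lp += -2.0 * np.log1p(sig**2 / sig_s2df) + log_s
            grad[p] += -4.0 * sig**2 / (sig_s2df + sig**2) + 1.0
            return lp, grad

        # least-squares-based initialization and mass guess
        beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid_sd = float(np.std(y - X @ beta_ls)) or 1.0
        base = np.concatenate([beta_ls, [np.log(resid_sd)]])
        inv0 = np.empty(p + 1)
        inv0[:p] = resid_sd**2 / np.maximum(np.diag(XtX), 1e-12)
        inv0[p] = 1.0 / (2.0 * n)

        def init(rng):
            return base + rng.uniform(-0.1, 0.1, p + 1) * np.sqrt(inv0)

        arr, stats = sample_chains(
            logp_grad,
            init,
            p + 1,
            self.chains,
            self.warmup,
            self.draws,
            seed=self.seed,
            target_accept=self.target_accept,
            init_inv_mass=inv0,
        )
        flat = arr.reshape(-1, p + 1)
        self.columns_ = list(columns)
        self.coef_draws_ = flat[:, :p]
        self.sigma_draws_ = np.exp(flat[:, p])
        self.sampler_stats_ = stats
        self.estimates_ = [
            AssociationEstimate(
                term=c,
                median=float(np.median(self.coef_draws_[:, j])),
                lower=credible_interval(self.coef_draws_[:, j])[0],
                upper=credible_interval(self.coef_draws_[:, j])[1],
                prob=compute_prob(self.coef_draws_[:, j]),
            )
            for j, c in enumerate(self.columns_)
            if c != "intercept"
        ]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Posterior-median prediction."""
        beta = np.median(self.coef_draws_, axis=0)
        return np.asarray(X, float) @ beta


def _second_stage_design(
    baseline: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    mains, names = encode_mains(baseline, covariates)
    X = np.column_stack([np.ones(len(baseline)), mains])
    return X, ["intercept"] + names


def fit_association(
    standardized: np.ndarray,
    baseline: pd.DataFrame,
    covariates: list[str],
    mode: str = "joint",
    **model_kwargs,
) -> list[AssociationEstimate]:
    """Regress standardized effects on baseline factors.

    ``mode="joint"`` (default) enters all covariates in one multivariable
    model; ``mode="univariable"`` fits one intercept+covariate model per
    covariate and concatenates the estimates.
    """
    y = np.asarray(standardized, float)
    if len(y) != len(baseline):
        raise ValueError("one standardized effect per participant is required")
    if mode == "joint":
        X, cols = _second_stage_design(baseline, covariates)
        return BayesianLinearRegression(**model_kwargs).fit(X, y, cols).estimates_
    if mode == "univariable":
        out: list[AssociationEstimate] = []
        for cov in covariates:
            X, cols = _second_stage_design(baseline, [cov])
            out.extend(
                BayesianLinearRegression(**model_kwargs).fit(X, y, cols).estimates_
            )
        return out
    raise ValueError(f"unknown mode {mode!r} (joint or univariable)")


def fit_interaction(
    standardized: np.ndarray,
    baseline: pd.DataFrame,
    pair: tuple[str, str],
    include_product: bool = True,
    **model_kwargs,
) -> list[AssociationEstimate]:
    """Two mains plus their product term, built from the same codings.

    Multi-column codings (e.g. a 3-level categorical) contribute one
    product column per coding-column pair.  With ``include_product=False``
    the model reduces exactly to the two-covariate main-effects fit.
    """
    cov_a, cov_b = pair
    y = np.asarray(standardized, float)
    ma, names_a = encode_mains(baseline, [cov_a])
    mb, names_b = encode_mains(baseline, [cov_b])
    prods = []
    prod_names = []
    if include_product:
        for i, na in enumerate(names_a):
            for j, nb in enumerate(names_b):
                prods.append(ma[:, i] * mb[:, j])
                prod_names.append(f"{na}:{nb}")
    X = np.column_stack([np.ones(len(baseline)), ma, mb] + prods)
    cols = ["intercept"] + names_a + names_b + prod_names
    return BayesianLinearRegression(**model_kwargs).fit(X, y, cols).estimates_


def association_table(estimates: list[AssociationEstimate]) -> pd.DataFrame:
    """Tables-style frame: term, estimate, CoI bounds, Prob (%)."""
    return pd.DataFrame([e.as_dict() for e in estimates]).rename(
        columns={"median": "estimate", "lower": "coi_lower", "upper": "coi_upper"}
    )
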