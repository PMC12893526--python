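"""Shared fixtures: small synthetic trials and one reusable reduced fit.

Simulation sizes here are chosen for test runtime; the recovery and
calibration studies with their full sizes live in test_acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pytest

from trialite.outcome_model import BayesianOutcomeModel
from trialite.simulate import (
    GeneratorConfig,
    OutcomeDGP,
    TrueDGP,
    simulate_trial,
)

REDUCED_COVARIATES = ["gender", "age", "importance"]


def make_config(n: int, seed: int = 0) -> GeneratorConfig:
    cfg = GeneratorConfig.default()
    cfg.n = n
    cfg.seed = seed
    return cfg


def reduced_dgp(
    group: float = 0.7,
    age_int: float = 0.02,
    man_int: float = 0.0,
    importance_int: float = 0.0,
    intercept: float = -1.0,
    sigma_u: float = 1.0,
    outcome: str = "prolonged",
) -> TrueDGP:
    """Truth restricted to the reduced covariate set used in fast fits."""
    inter = {
        k: v
        for k, v in
        {"age": age_int, "man": man_int, "importance": importance_int}.items()
        if v != 0.0
    }
    return TrueDGP(
        outcomes={
            outcome: OutcomeDGP(
                intercept=intercept,
                time=-0.1,
                group=group,
                main={"age": 0.01},
                interaction=inter,
                sigma_u=sigma_u,
            )
        }
    )


@pytest.fixture(scope="session")
def small_trial():
    """Default-config trial, n=300, both outcomes, with missingness."""
    ds, truth = simulate_trial(make_config(300), seed=42)
    return ds, truth


@pytest.fixture(scope="session")
def fitted_small(small_trial):
    """One reduced-scale fitted outcome model shared across tests."""
    ds, _ = small_trial
    model = BayesianOutcomeModel(
        covariates=REDUCED_COVARIATES,
        chains=2,
        warmup=200,
        draws=200,
        seed=7,
    ).fit(ds, "prolonged")
    return ds, model


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
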