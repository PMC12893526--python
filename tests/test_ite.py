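"""ITE engine: counterfactual contrasts, oracles, and summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from trialite.design import Design, main_effect_columns
from trialite.ite import ITETable, compute_ite, predict_probability, summarize_ite
from trialite.outcome_model import BayesianOutcomeModel, PosteriorDraws
from trialite.simulate import generate_baseline

from conftest import make_config


def make_model_with_draws(baseline, covariates, coef_rows, seed=0):
    """Assemble a prediction-ready model from explicit coefficient draws.

    ``coef_rows``: (S, p) array over [intercept, time, group, time:group,
    mains..., group:mains...] on the natural scale.
    """
    names = main_effect_columns(covariates)
    columns = (
        ["intercept", "time", "group", "time:group"]
        + names
        + [f"group:{c}" for c in names]
    )
    coef = np.asarray(coef_rows, float)
    S, p = coef.shape
    assert p == len(columns)
    ids = baseline["participant_id"].tolist()
    centers = {
        c: float(baseline[c].mean())
        for c in covariates
        if baseline[c].dtype.kind in "fi"
    }
    packed = np.concatenate(
        [coef, np.full((S, 1), 0.5), np.full((S, 1), 0.1), np.zeros((S, len(ids)))],
        axis=1,
    )[None, :, :]
    model = BayesianOutcomeModel()
    model.outcome_ = "prolonged"
    model.counterfactual = "zero"
    model.draws_ = PosteriorDraws(
        chains_array=packed,
        names=columns + ["sigma_u", "tau"] + [f"u[{i}]" for i in ids],
        n_fixed=p,
        seed=seed,
        n_warmup=0,
    )
    model.design_ = Design(
        X=np.empty((0, p)),
        y=np.empty(0),
        columns=columns,
        participant_index=np.empty(0, int),
        participant_ids=ids,
        centers=centers,
        covariates=list(covariates),
        outcome="prolonged",
        idx_mains=slice(4, 4 + len(names)),
        idx_interactions=slice(4 + len(names), p),
    )
    return model


@pytest.fixture(scope="module")
def profiles():
    return generate_baseline(make_config(50), seed=3)


def test_all_zero_draws_give_half_probability_and_zero_delta(profiles):
    model = make_model_with_draws(profiles, ["age"], np.zeros((10, 6)))
    p = predict_probability(model, profiles, 1, "3mo")
    assert np.allclose(p, 0.5)
    ite = compute_ite(model, profiles, "3mo")
    assert np.all(ite.samples == 0.0)
    assert np.all(ite.point_estimates == 0.0)


def test_single_draw_hand_computed_oracle(profiles):
    # intercept .3, time -.2, group .4, time:group .1, age main .02, g:age .05
    coef = np.array([[0.3, -0.2, 0.4, 0.1, 0.02, 0.05]])
    model = make_model_with_draws(profiles, ["age"], coef)
    age_c = profiles.age.to_numpy() - profiles.age.mean()
    for tp, t in (("3mo", 0.0), ("6mo", 1.0)):
        eta1 = 0.3 - 0.2 * t + 0.4 + 0.1 * t + 0.02 * age_c + 0.05 * age_c
        eta0 = 0.3 - 0.2 * t + 0.02 * age_c
        expected = expit(eta1) - expit(eta0)
        ite = compute_ite(model, profiles, tp)
        assert np.allclose(ite.samples[0], expected)
        assert np.allclose(ite.point_estimates, expected)  # single draw


def test_identical_profiles_identical_deltas(profiles, rng):
    coef = rng.normal(0, 0.3, (40, 6))
    model = make_model_with_draws(profiles, ["age"], coef)
    twin = pd.concat([profiles.iloc[[0]], profiles.iloc[[0]]], ignore_index=True)
    twin["participant_id"] = [model.design_.participant_ids[0]] * 2
    ite = compute_ite(model, twin, "3mo")
    assert np.array_equal(ite.samples[:, 0], ite.samples[:, 1])


def test_treatment_relevant_covariates_differentiate(profiles, rng):
    coef = np.zeros((30, 6))
    coef[:, 5] = rng.normal(0.1, 0.02, 30)  # only group:age nonzero
    model = make_model_with_draws(profiles, ["age"], coef)
    ite = compute_ite(model, profiles, "3mo")
    ages = profiles.age.round(6)
    med = pd.Series(ite.point_estimates, index=profiles.index)
    assert med[ages.idxmax()] != med[ages.idxmin()]


def test_arm_antisymmetry(profiles, rng):
    coef = rng.normal(0, 0.4, (25, 6))
    model = make_model_with_draws(profiles, ["age"], coef)
    p1 = predict_probability(model, profiles, 1, "6mo")
    p0 = predict_probability(model, profiles, 0, "6mo")
    assert np.array_equal(p1 - p0, -(p0 - p1))
    assert np.all((p1 > 0) & (p1 < 1) & (p0 > 0) & (p0 < 1))


def test_delta_bounds_and_median_within_interval(fitted_small):
    ds, model = fitted_small
    ite = compute_ite(model, ds.baseline, "3mo")
    assert ite.samples.min() >= -1.0 and ite.samples.max() <= 1.0
    lo, hi = np.percentile(ite.samples, [2.5, 97.5], axis=0)
    assert np.all(lo <= ite.point_estimates) and np.all(ite.point_estimates <= hi)
    # computed for ALL randomized participants, missing outcomes included
    assert ite.samples.shape[1] == ds.n_participants


class TestSummarize:
    def test_all_zero(self, profiles):
        model = make_model_with_draws(profiles, ["age"], np.zeros((5, 6)))
        s = summarize_ite(compute_ite(model, profiles, "3mo"))
        assert s.mean_pp == 0.0 and s.sd_pp == 0.0

    def test_percentage_point_arithmetic(self):
        table = ITETable(
            outcome="prolonged",
            timepoint="3mo",
            participant_ids=["a", "b"],
            samples=np.array([[0.01, 0.03]]),
            point_estimates=np.array([0.01, 0.03]),
            counterfactual="zero",
        )
        s = summarize_ite(table)
        assert s.mean_pp == pytest.approx(2.0)
        assert s.sd_pp == pytest.approx(100 * np.std([0.01, 0.03], ddof=1))

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_ite([])
        from trialite.ite import ITEResult

        mixed = [
            ITEResult("a", "prolonged", "3mo", np.array([0.0]), 0.0),
            ITEResult("b", "prolonged", "6mo", np.array([0.0]), 0.0),
        ]
        with pytest.raises(ValueError, match="mixed"):
            summarize_ite(mixed)

    def test_csv_roundtrip_summary(self, tmp_path, profiles, rng):
        coef = rng.normal(0, 0.3, (40, 6))
        model = make_model_with_draws(profiles, ["age"], coef)
        ite = compute_ite(model, profiles, "6mo")
        path = tmp_path / "ite.csv"
        ite.to_frame().to_csv(path, index=False)
        back = pd.read_csv(path)
        s1 = summarize_ite(ite)
        pts = back.point_estimate.to_numpy()
        assert 100 * pts.mean() == pytest.approx(s1.mean_pp)
        assert 100 * pts.std(ddof=1) == pytest.approx(s1.sd_pp)
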