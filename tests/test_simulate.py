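"""Synthetic-trial generator: marginal fidelity, randomization balance,
closed-form effects, outcome generation, and missingness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from trialite.dataset import TIMEPOINTS
from trialite.simulate import (
    ConfigError,
    GeneratorConfig,
    MissingnessDGP,
    OutcomeDGP,
    TrueDGP,
    apply_missingness,
    expected_response_rates,
    generate_baseline,
    generate_outcomes,
    nexit_like_dgp,
    null_dgp,
    randomize,
    simulate_trial,
    true_ite,
)

from conftest import make_config


class TestGenerateBaseline:
    def test_default_marginals_at_trial_size(self):
        b = generate_baseline(make_config(1012), seed=1)
        assert len(b) == 1012
        # binomial sampling error around the configured 81% women
        p = (b.gender == "woman").mean()
        assert abs(p - 0.81) < 3 * np.sqrt(0.81 * 0.19 / 1012)
        assert abs(b.age.mean() - 45.4) < 3 * 14.0 / np.sqrt(1012)

    def test_invariants_hold_rowwise(self):
        b = generate_baseline(make_config(800), seed=2)
        for col in ("importance", "confidence", "knowhow", "fagerstrom"):
            assert b[col].between(0, 10).all()
        assert (b.years_smoking < b.age).all()
        assert (b.years_smoking >= 0).all()
        assert b.snus_use.isin(["daily", "weekly_or_monthly", "none"]).all()
        assert b.counseling.isin(["no", "yes_past", "yes_now"]).all()
        assert (b.quit_attempts == b.quit_attempts.round()).all()

    def test_empty_and_determinism(self):
        cfg = make_config(0)
        assert len(generate_baseline(cfg, seed=3)) == 0
        cfg = make_config(150)
        b1 = generate_baseline(cfg, seed=9)
        b2 = generate_baseline(cfg, seed=9)
        pd.testing.assert_frame_equal(b1, b2)
        b3 = generate_baseline(cfg, seed=10)
        assert not b1.equals(b3)

    def test_invalid_proportions_rejected(self):
        cfg = make_config(10)
        cfg.marginals["snus_use"]["probs"] = [0.5, 0.2, 0.2]
        with pytest.raises(ConfigError, match="sum"):
            generate_baseline(cfg)

    def test_negative_n_rejected(self):
        with pytest.raises(ConfigError, match="non-negative"):
            generate_baseline(make_config(-5))

    def test_infeasible_moment_pair_rejected(self):
        cfg = make_config(10)
        # no Beta on [0, 10] has mean 9.9 with SD 3 (variance exceeds bound)
        cfg.marginals["importance"] = {
            "kind": "beta", "mean": 9.9, "sd": 3.0, "lower": 0.0, "upper": 10.0,
        }
        with pytest.raises(ConfigError, match="Beta"):
            generate_baseline(cfg)

    def test_correlation_hook(self):
        cfg = make_config(4000)
        cfg.correlation = [["age", "confidence", -0.5]]
        b = generate_baseline(cfg, seed=4)
        r = np.corrcoef(b.age, b.confidence)[0, 1]
        assert r < -0.3  # copula correlation propagates (attenuated by ppf)


class TestRandomize:
    def test_complete_block_balance(self):
        cfg = make_config(4)
        cfg.block_sizes = [4]
        b = generate_baseline(cfg, seed=5)
        b["elective_surgery"] = False  # one stratum of exactly one block
        alloc = randomize(b, cfg, seed=6)
        assert alloc.sum() == 2

    def test_stratified_imbalance_bound(self):
        cfg = make_config(1012)
        b = generate_baseline(cfg, seed=7)
        alloc = randomize(b, cfg, seed=8)
        strata = b.groupby("elective_surgery")["participant_id"]
        assert len(strata) == 2
        for _, ids in strata:
            g = alloc.loc[ids]
            assert abs(2 * g.sum() - len(g)) <= max(cfg.block_sizes)

    def test_determinism_and_unknown_stratum(self):
        cfg = make_config(120)
        b = generate_baseline(cfg, seed=1)
        pd.testing.assert_series_equal(
            randomize(b, cfg, seed=2), randomize(b, cfg, seed=2)
        )
        cfg.strata = "not_a_column"
        with pytest.raises(ConfigError, match="not_a_column"):
            randomize(b, cfg, seed=2)

    def test_odd_block_size_rejected(self):
        cfg = make_config(10)
        cfg.block_sizes = [3]
        with pytest.raises(ConfigError, match="even"):
            cfg.validate()


class TestTrueIte:
    def test_null_dgp_gives_zero_everywhere(self):
        b = generate_baseline(make_config(50), seed=1)
        d = true_ite(null_dgp(), b, "3mo", "prolonged")
        assert np.allclose(d, 0.0)

    def test_inverse_logit_arithmetic_oracle(self):
        # control predictor 0, treatment adds +1.0
        dgp = TrueDGP(outcomes={"prolonged": OutcomeDGP(intercept=0.0, group=1.0)})
        b = generate_baseline(make_config(20), seed=2)
        d = true_ite(dgp, b, "3mo", "prolonged")
        assert np.allclose(d, expit(1.0) - expit(0.0))

    def test_sign_flip_symmetry(self):
        b = generate_baseline(make_config(40), seed=3)
        pos = TrueDGP(outcomes={"prolonged": OutcomeDGP(
            group=0.5, time_group=0.2, interaction={"age": 0.03, "man": -0.4})})
        neg = TrueDGP(outcomes={"prolonged": OutcomeDGP(
            group=-0.5, time_group=-0.2, interaction={"age": -0.03, "man": 0.4})})
        for tp in TIMEPOINTS:
            d1 = true_ite(pos, b, tp, "prolonged")
            d2 = true_ite(neg, b, tp, "prolonged")
            assert np.allclose(d1, -d2)

    def test_unknown_covariate_in_dgp_rejected(self):
        b = generate_baseline(make_config(10), seed=4)
        dgp = TrueDGP(outcomes={"prolonged": OutcomeDGP(main={"nonesuch": 1.0})})
        with pytest.raises(ConfigError, match="nonesuch"):
            true_ite(dgp, b, "3mo", "prolonged")

    @given(
        group=st.floats(-3, 3),
        age_int=st.floats(-0.1, 0.1),
        intercept=st.floats(-4, 4),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_delta_bounded(self, group, age_int, intercept):
        b = generate_baseline(make_config(30), seed=5)
        dgp = TrueDGP(outcomes={"prolonged": OutcomeDGP(
            intercept=intercept, group=group, interaction={"age": age_int})})
        d = true_ite(dgp, b, "6mo", "prolonged")
        assert np.all(d >= -1.0) and np.all(d <= 1.0)


class TestGenerateOutcomes:
    def test_saturated_null(self):
        cfg = make_config(1012)
        b = generate_baseline(cfg, seed=1)
        alloc = randomize(b, cfg, seed=2)
        dgp = TrueDGP(outcomes={"prolonged": OutcomeDGP(intercept=-10.0, sigma_u=0.0)})
        oc, _ = generate_outcomes(b, alloc, dgp, seed=3)
        assert oc.value.sum() == 0  # expit(-10) ~ 5e-5: all zeros at this n

    def test_no_clustering_matches_independence_oracle(self):
        # with sigma_u = 0 the two timepoints are independent given covariates
        cfg = make_config(50_000)
        b = generate_baseline(cfg, seed=4)
        alloc = pd.Series(0, index=b.participant_id)
        dgp = TrueDGP(outcomes={"prolonged": OutcomeDGP(intercept=-0.5, sigma_u=0.0)})
        oc, _ = generate_outcomes(b, alloc, dgp, seed=5)
        wide = oc.pivot(index="participant_id", columns="timepoint", values="value")
        tab = pd.crosstab(wide["3mo"], wide["6mo"]).to_numpy(float)
        odds_ratio = (tab[0, 0] * tab[1, 1]) / (tab[0, 1] * tab[1, 0])
        se = np.sqrt((1.0 / tab).sum())
        assert abs(np.log(odds_ratio)) < 3 * se

    def test_clustering_raises_within_participant_association(self):
        cfg = make_config(20_000)
        b = generate_baseline(cfg, seed=6)
        alloc = pd.Series(0, index=b.participant_id)
        dgp = TrueDGP(outcomes={"prolonged": OutcomeDGP(intercept=-0.5, sigma_u=1.5)})
        oc, _ = generate_outcomes(b, alloc, dgp, seed=7)
        wide = oc.pivot(index="participant_id", columns="timepoint", values="value")
        tab = pd.crosstab(wide["3mo"], wide["6mo"]).to_numpy(float)
        assert np.log((tab[0, 0] * tab[1, 1]) / (tab[0, 1] * tab[1, 0])) > 0.3

    def test_determinism_and_truth_attached(self):
        cfg = make_config(100)
        b = generate_baseline(cfg, seed=8)
        alloc = randomize(b, cfg, seed=9)
        oc1, t1 = generate_outcomes(b, alloc, nexit_like_dgp(), seed=10)
        oc2, t2 = generate_outcomes(b, alloc, nexit_like_dgp(), seed=10)
        pd.testing.assert_frame_equal(oc1, oc2)
        pd.testing.assert_frame_equal(t1.deltas, t2.deltas)
        assert t1.deltas.delta.between(-1, 1).all()
        # 2 outcomes x 2 timepoints x 100 participants
        assert len(oc1) == 400 and len(t1.deltas) == 400

    def test_null_dgp_arm_difference_within_mc_error(self):
        cfg = make_config(20_000)
        b = generate_baseline(cfg, seed=11)
        alloc = randomize(b, cfg, seed=12)
        oc, _ = generate_outcomes(b, alloc, null_dgp(), seed=13)
        oc["group"] = oc.participant_id.map(alloc)
        sub = oc[(oc.outcome == "prolonged") & (oc.timepoint == "3mo")]
        p1 = sub[sub.group == 1].value.mean()
        p0 = sub[sub.group == 0].value.mean()
        n1, n0 = (sub.group == 1).sum(), (sub.group == 0).sum()
        se = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
        assert abs(p1 - p0) < 3 * se


class TestApplyMissingness:
    def test_certain_response_leaves_everything_observed(self):
        ds, _ = simulate_trial(make_config(200), seed=1, missingness=False)
        dgp = nexit_like_dgp()
        dgp.missingness = MissingnessDGP(
            intercept={"3mo": 50.0, "6mo": 50.0},
            arm={"3mo": 0.0, "6mo": 0.0},
            age={"3mo": 0.0, "6mo": 0.0},
        )
        out = apply_missingness(ds.outcomes, ds.baseline, ds.allocation, dgp, seed=2)
        assert out.value.notna().all()

    def test_response_rates_near_configured_targets(self):
        cfg = make_config(1012)
        ds, _ = simulate_trial(cfg, seed=3, missingness=False)
        dgp = nexit_like_dgp()
        out = apply_missingness(ds.outcomes, ds.baseline, ds.allocation, dgp, seed=4)
        targets = expected_response_rates(dgp, ds.baseline, ds.allocation)
        g = ds.allocation
        for tp in TIMEPOINTS:
            sub = out[(out.timepoint == tp) & (out.outcome == "prolonged")]
            for arm in (0, 1):
                ids = g[g == arm].index
                obs = sub[sub.participant_id.isin(ids)].value.notna().mean()
                t = targets[tp][arm]
                se = np.sqrt(t * (1 - t) / len(ids))
                assert abs(obs - t) < 3 * se
        # default targets sit in the trial's reported band
        assert 0.60 < targets["3mo"][1] < targets["3mo"][0] < 0.72
        assert 0.60 < targets["6mo"][0] < 0.68

    def test_six_month_response_is_age_associated(self):
        import statsmodels.api as sm

        cfg = make_config(8000)
        ds, _ = simulate_trial(cfg, seed=5, missingness=False)
        dgp = nexit_like_dgp()
        out = apply_missingness(ds.outcomes, ds.baseline, ds.allocation, dgp, seed=6)
        sub = out[(out.timepoint == "6mo") & (out.outcome == "prolonged")]
        resp = sub.set_index("participant_id").value.notna().astype(float)
        age = ds.baseline.set_index("participant_id").age.loc[resp.index]
        fitted = sm.Logit(resp.to_numpy(), sm.add_constant(age.to_numpy())).fit(disp=0)
        coef, se = fitted.params[1], fitted.bse[1]
        assert coef > 0 and coef - 2 * se > 0
        # recovered magnitude near the configured 0.02 per year
        assert abs(coef - dgp.missingness.age["6mo"]) < 3 * se

    def test_both_outcomes_missing_together(self):
        ds, _ = simulate_trial(make_config(400), seed=7)
        wide = ds.outcomes.pivot_table(
            index=["participant_id", "timepoint"],
            columns="outcome",
            values="value",
            dropna=False,
        )
        assert (wide["prolonged"].isna() == wide["point_prevalence"].isna()).all()


def test_simulate_trial_roundtrip_truth(small_trial):
    ds, truth = small_trial
    ds.validate()
    d = truth.delta("prolonged", "3mo")
    assert len(d) == ds.n_participants
    assert d.between(-1, 1).all()
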