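"""Second-stage association models and exact post-processing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialite.association import (
    BayesianLinearRegression,
    compute_prob,
    credible_interval,
    fit_association,
    fit_interaction,
    standardize_effects,
)
from trialite.design import DegenerateDesignError
from trialite.simulate import generate_baseline

from conftest import make_config


class TestStandardize:
    def test_definition(self):
        z = standardize_effects([1.0, 3.0])
        assert z == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])
        x = np.random.default_rng(0).normal(2, 5, 200)
        z = standardize_effects(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="zero spread"):
            standardize_effects([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="at least 2"):
            standardize_effects([1.0])

    def test_idempotent(self):
        x = np.random.default_rng(1).normal(size=50)
        z = standardize_effects(x)
        assert np.allclose(standardize_effects(z), z)


class TestProb:
    def test_counting(self):
        assert compute_prob([-1, 1, 1, 1]) == 75.0
        assert compute_prob([1, 2, 3]) == 100.0
        assert compute_prob([-3, -1, 1, 3]) == 50.0
        assert compute_prob([-1, -2, -3, 5]) == 75.0  # negative median side

    def test_zeros_count_to_neither_side(self):
        assert compute_prob([0.0, 0.0, 1.0, 2.0]) == 50.0

    def test_empty(self):
        with pytest.raises(ValueError):
            compute_prob([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_brute_force_agreement(self, xs):
        s = np.array(xs)
        p = compute_prob(s)
        m = sorted(xs)[len(xs) // 2] if len(xs) % 2 else np.median(s)
        n_pos = sum(1 for v in xs if v > 0)
        n_neg = sum(1 for v in xs if v < 0)
        brute = 100.0 * ((n_pos if m >= 0 else n_neg) / len(xs))
        assert p == brute
        assert 0.0 <= p <= 100.0


class TestCredibleInterval:
    def test_percentile_oracle_1_to_1000(self):
        s = np.arange(1, 1001, dtype=float)
        lo, hi = credible_interval(s)
        # brute-force sort-and-interpolate under the linear convention
        def brute(q):
            v = np.sort(s)
            h = (len(v) - 1) * q / 100.0
            f = int(np.floor(h))
            return v[f] + (h - f) * (v[min(f + 1, len(v) - 1)] - v[f])
        assert lo == pytest.approx(brute(2.5)) == pytest.approx(25.975)
        assert hi == pytest.approx(brute(97.5)) == pytest.approx(975.025)

    def test_constant_and_order(self):
        assert credible_interval([3.0, 3.0, 3.0]) == (3.0, 3.0)
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.normal(size=rng.integers(1, 50))
            lo, hi = credible_interval(s)
            assert lo <= hi

    def test_empty(self):
        with pytest.raises(ValueError):
            credible_interval([])


@pytest.fixture(scope="module")
def baseline():
    return generate_baseline(make_config(800), seed=17)


class TestFitAssociation:
    def test_recovers_planted_signal(self, baseline):
        rng = np.random.default_rng(3)
        age_c = baseline.age - baseline.age.mean()
        y = 0.05 * age_c + rng.normal(0, 0.5, len(baseline))
        z = standardize_effects(y)
        est = fit_association(
            z, baseline, ["gender", "age"], seed=1, chains=1, warmup=300, draws=300
        )
        by = {e.term: e for e in est}
        # standardization rescales: true slope 0.05/sd(y)
        target = 0.05 / np.std(y, ddof=1)
        assert by["age"].median == pytest.approx(target, abs=0.01)
        assert by["age"].prob > 97.5
        assert by["age"].lower <= by["age"].median <= by["age"].upper

    def test_determinism_and_modes(self, baseline):
        rng = np.random.default_rng(4)
        z = standardize_effects(rng.normal(size=len(baseline)))
        kw = dict(seed=5, chains=1, warmup=150, draws=150)
        e1 = fit_association(z, baseline, ["gender", "age"], **kw)
        e2 = fit_association(z, baseline, ["gender", "age"], **kw)
        assert [a.as_dict() for a in e1] == [a.as_dict() for a in e2]
        uni = fit_association(z, baseline, ["gender", "age"], mode="univariable", **kw)
        assert [e.term for e in uni] == ["man", "age"]
        with pytest.raises(ValueError, match="mode"):
            fit_association(z, baseline, ["age"], mode="nonesuch")

    def test_rank_deficient_rejected(self, baseline):
        z = standardize_effects(np.random.default_rng(5).normal(size=len(baseline)))
        X = np.column_stack([np.ones(len(z)), z, z])  # duplicated column
        with pytest.raises(DegenerateDesignError):
            BayesianLinearRegression(chains=1, warmup=50, draws=50).fit(X, z)


class TestFitInteraction:
    def test_nesting_consistency(self, baseline):
        rng = np.random.default_rng(6)
        z = standardize_effects(rng.normal(size=len(baseline)))
        kw = dict(seed=9, chains=1, warmup=150, draws=150)
        no_prod = fit_interaction(
            z, baseline, ("gender", "importance"), include_product=False, **kw
        )
        joint = fit_association(z, baseline, ["gender", "importance"], **kw)
        assert [a.as_dict() for a in no_prod] == [a.as_dict() for a in joint]

    def test_product_term_detects_level_specific_effect(self, baseline):
        rng = np.random.default_rng(7)
        man = (baseline.gender == "man").to_numpy(float)
        imp_c = (baseline.importance - baseline.importance.mean()).to_numpy()
        y = 0.4 * man * imp_c + rng.normal(0, 0.6, len(baseline))
        z = standardize_effects(y)
        est = fit_interaction(
            z, baseline, ("gender", "importance"),
            seed=11, chains=1, warmup=250, draws=250,
        )
        by = {e.term: e for e in est}
        prod = by["man:importance"]
        assert prod.lower > 0  # CoI excludes 0 at this effect size
        assert prod.prob > 99

    def test_estimates_exclude_intercept_and_include_product(self, baseline):
        z = standardize_effects(
            np.random.default_rng(8).normal(size=len(baseline))
        )
        est = fit_interaction(
            z, baseline, ("gender", "importance"),
            seed=12, chains=1, warmup=100, draws=100,
        )
        terms = [e.term for e in est]
        assert terms == ["man", "importance", "man:importance"]


def test_estimates_match_brute_force_postprocessing(baseline):
    rng = np.random.default_rng(13)
    z = standardize_effects(rng.normal(size=len(baseline)))
    model = BayesianLinearRegression(chains=1, warmup=100, draws=150, seed=3)
    X = np.column_stack(
        [np.ones(len(z)), (baseline.age - baseline.age.mean()).to_numpy()]
    )
    model.fit(X, z, ["intercept", "age"])
    (est,) = model.estimates_
    col = model.coef_draws_[:, 1]
    assert est.median == float(np.median(col))
    assert (est.lower, est.upper) == credible_interval(col)
    assert est.prob == compute_prob(col)
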