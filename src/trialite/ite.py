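"""Individualized treatment effects from posterior counterfactuals.

For participant i with baseline covariates x_i, the individualized effect

    delta(x_i) = P(Y=1 | G=1, x=x_i) - P(Y=1 | G=0, x=x_i)

is computed draw-wise from the outcome model's posterior: every MCMC draw
yields one delta sample per participant, giving a posterior distribution
over each participant's effect; the posterior median is the point estimate.
Effects are computed for *all* randomized participants, including those
with missing follow-up outcomes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .outcome_model import BayesianOutcomeModel

__all__ = [
    "ITEResult",
    "ITETable",
    "ITESummary",
    "predict_probability",
    "compute_ite",
    "summarize_ite",
]


@dataclasses.dataclass
class ITEResult:
    """Posterior of delta(x_i) for one participant at one outcome/timepoint."""

    participant_id: object
    outcome: str
    timepoint: str
    sample: np.ndarray  # (S,) probability differences
    point_estimate: float  # posterior median of ``sample``

    def quantile(self, q) -> np.ndarray:
        return np.percentile(self.sample, q)


@dataclasses.dataclass
class ITETable:
    """All participants' delta posteriors for one outcome x timepoint.

    ``samples`` has shape (S, n) in probability-difference units;
    ``point_estimates`` are the column medians.
    """

    outcome: str
    timepoint: str
    participant_ids: list
    samples: np.ndarray
    point_estimates: np.ndarray
    counterfactual: str  # adaptive-intercept convention used

    @property
    def results(self) -> list[ITEResult]:
        return [
            ITEResult(
                participant_id=pid,
                outcome=self.outcome,
                timepoint=self.timepoint,
                sample=self.samples[:, j],
                point_estimate=float(self.point_estimates[j]),
            )
            for j, pid in enumerate(self.participant_ids)
        ]

    def to_frame(self) -> pd.DataFrame:
        lo, hi = np.percentile(self.samples, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "outcome": self.outcome,
                "timepoint": self.timepoint,
                "point_estimate": self.point_estimates,
                "q2.5": lo,
                "q97.5": hi,
            }
        )


@dataclasses.dataclass
class ITESummary:
    """Cohort-level distribution summary, in percentage points."""

    outcome: str
    timepoint: str
    mean_pp: float
    sd_pp: float
    n: int
    bin_edges: np.ndarray  # percentage-point histogram bins
    bin_counts: np.ndarray


def predict_probability(
    model: BayesianOutcomeModel,
    profiles: pd.DataFrame,
    arm: int,
    timepoint: str,
) -> np.ndarray:
    """Per-draw counterfactual probabilities, shape (S, n); see
    :meth:`BayesianOutcomeModel.predict_proba`."""
    return model.predict_proba(profiles, arm=arm, timepoint=timepoint)


def compute_ite(
    model: BayesianOutcomeModel,
    profiles: pd.DataFrame,
    timepoint: str,
) -> ITETable:
    """Draw-wise counterfactual contrast for every profile.

    The same posterior draw (and, under the ``"draws"`` or ``"marginal"``
    conventions, the same adaptive-intercept value) is used on both sides
    of the contrast, so the arms differ only in allocation.
    """
    p1 = predict_probability(model, profiles, arm=1, timepoint=timepoint)
    p0 = predict_probability(model, profiles, arm=0, timepoint=timepoint)
    delta = p1 - p0
    return ITETable(
        outcome=model.outcome_,
        timepoint=timepoint,
        participant_ids=profiles["participant_id"].tolist(),
        samples=delta,
        point_estimates=np.median(delta, axis=0),
        counterfactual=model.counterfactual,
    )


def summarize_ite(
    results: ITETable | list[ITEResult], n_bins: int = 30
) -> ITESummary:
    """Mean and SD of the delta point estimates, in percentage points,
    plus histogram data for the distribution plot."""
    if isinstance(results, ITETable):
        pts = np.asarray(results.point_estimates, float)
        outcome, timepoint = results.outcome, results.timepoint
    else:
        if not results:
            raise ValueError("empty ITE results")
        keys = {(r.outcome, r.timepoint) for r in results}
        if len(keys) != 1:
            raise ValueError(f"mixed outcome x timepoint in summary: {sorted(keys)}")
        (outcome, timepoint) = keys.pop()
        pts = np.array([r.point_estimate for r in results], float)
    if pts.size == 0:
        raise ValueError("empty ITE results")
    pp = 100.0 * pts
    counts, edges = np.histogram(pp, bins=n_bins)
    return ITESummary(
        outcome=outcome,
        timepoint=timepoint,
        mean_pp=float(np.mean(pp)),
        sd_pp=float(np.std(pp, ddof=1)) if pp.size > 1 else 0.0,
        n=int(pp.size),
        bin_edges=edges,
        bin_counts=counts,
    )
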