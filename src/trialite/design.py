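"""Model-matrix construction for the outcome and association models.

Coding conventions (fixed across the package so that simulator truth,
outcome model, and second-stage regressions all speak the same language):

* categoricals are dummy-coded against the references woman, snus ``daily``,
  counseling ``no``, and ``primary_care`` recruitment, giving the contrasts
  man-vs-woman, weekly-or-monthly-vs-daily, none-vs-daily, past/current
  support-vs-none, online-vs-primary-care;
* flags enter as 0/1;
* continuous covariates are centered (by default at the baseline-sample
  mean over all randomized participants) but not rescaled, so coefficients
  are per natural unit (e.g. per year of age).

The outcome-model term list is: intercept, time (6-month indicator), group,
time x group, covariate main effects, covariate x group interactions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dataset import (
    CATEGORICAL_LEVELS,
    CONTINUOUS_COLUMNS,
    FLAG_COLUMNS,
    OUTCOMES,
    TIMEPOINTS,
    TrialDataset,
)

__all__ = [
    "DesignSpec",
    "Design",
    "DegenerateDesignError",
    "ALL_COVARIATES",
    "encode_mains",
    "main_effect_columns",
    "build_design",
]

#: Default covariate set: every baseline factor of the trial.
ALL_COVARIATES = [
    "gender",
    "age",
    "years_smoking",
    "daily_smoker",
    "cigarettes_per_week",
    "snus_use",
    "fagerstrom",
    "quit_attempts",
    "counseling",
    "used_quitline",
    "importance",
    "confidence",
    "knowhow",
    "elective_surgery",
    "setting",
]

#: Dummy-column names per categorical covariate (reference level omitted).
_DUMMY_COLUMNS = {
    "gender": [("man", "man")],
    "snus_use": [
        ("snus_weekly_or_monthly", "weekly_or_monthly"),
        ("snus_none", "none"),
    ],
    "counseling": [
        ("counseling_past", "yes_past"),
        ("counseling_now", "yes_now"),
    ],
    "setting": [("online", "online")],
}


class DegenerateDesignError(ValueError):
    """The requested design matrix is rank-deficient or constant."""


def main_effect_columns(covariates: list[str]) -> list[str]:
    """Design column names contributed by a list of baseline covariates."""
    cols: list[str] = []
    for cov in covariates:
        if cov in _DUMMY_COLUMNS:
            cols.extend(name for name, _ in _DUMMY_COLUMNS[cov])
        elif cov in FLAG_COLUMNS or cov in CONTINUOUS_COLUMNS:
            cols.append(cov)
        else:
            raise KeyError(f"unknown covariate {cov!r}")
    return cols


def encode_mains(
    baseline: pd.DataFrame,
    covariates: list[str],
    centers: dict[str, float] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Encode baseline covariates as a (n, k) main-effect matrix.

    ``centers`` maps continuous covariate names to centering constants; a
    missing entry means the covariate is centered at its mean in ``baseline``.
    """
    centers = centers or {}
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in baseline.columns:
            raise KeyError(f"covariate {cov!r} not in baseline table")
        if cov in _DUMMY_COLUMNS:
            for name, level in _DUMMY_COLUMNS[cov]:
                cols.append((baseline[cov] == level).to_numpy(float))
                names.append(name)
        elif cov in FLAG_COLUMNS:
            cols.append(baseline[cov].to_numpy(float))
            names.append(cov)
        else:
            x = baseline[cov].to_numpy(float)
            c = centers.get(cov, float(np.mean(x)) if len(x) else 0.0)
            cols.append(x - c)
            names.append(cov)
    mat = np.column_stack(cols) if cols else np.empty((len(baseline), 0))
    return mat, names


@dataclasses.dataclass
class DesignSpec:
    """Term plan for the outcome model.

    Every covariate appears exactly once as a main effect and once in an
    interaction with group allocation; time enters as a 6-month indicator
    with a single time x group term.
    """

    covariates: list[str] = dataclasses.field(
        default_factory=lambda: list(ALL_COVARIATES)
    )
    centers: dict[str, float] | None = None  # None -> baseline-sample means


@dataclasses.dataclass
class Design:
    """Realized design for one outcome: matrices plus encoding metadata."""

    X: np.ndarray  # (rows, p) fixed-effect matrix
    y: np.ndarray  # (rows,) binary response
    columns: list[str]
    participant_index: np.ndarray  # (rows,) position into participant_ids
    participant_ids: list
    centers: dict[str, float]
    covariates: list[str]
    outcome: str
    #: column-index slices for the term blocks
    idx_intercept: int = 0
    idx_time: int = 1
    idx_group: int = 2
    idx_time_group: int = 3
    idx_mains: slice = dataclasses.field(default_factory=lambda: slice(0, 0))
    idx_interactions: slice = dataclasses.field(default_factory=lambda: slice(0, 0))

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def encode_profiles(
        self, baseline: pd.DataFrame, arm: int, timepoint: str
    ) -> np.ndarray:
        """Encode profiles for counterfactual prediction at one arm/timepoint.

        Uses the centering constants frozen at fit time; raises KeyError if a
        required covariate is absent (profile/design coding mismatch).
        """
        if timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        if arm not in (0, 1):
            raise ValueError("arm must be 0 or 1")
        mains, names = encode_mains(baseline, self.covariates, self.centers)
        if names != self.columns[4 : 4 + len(names)]:
            raise ValueError("profile encoding does not match fitted design")
        n = len(baseline)
        t = float(timepoint == "6mo")
        head = np.column_stack(
            [
                np.ones(n),
                np.full(n, t),
                np.full(n, float(arm)),
                np.full(n, t * arm),
            ]
        )
        return np.concatenate([head, mains, arm * mains], axis=1)


def build_design(
    dataset: TrialDataset, outcome: str, spec: DesignSpec | None = None
) -> Design:
    """Build the outcome-model design from non-missing records.

    Rows are observed participant x timepoint records of the selected
    outcome only; all randomized participants define the centering sample
    even if they contributed no observed rows.
    """
    spec = spec or DesignSpec()
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r} (allowed: {OUTCOMES})")
    rec = dataset.observed(outcome)
    if not len(rec):
        raise ValueError(f"no observed records for outcome {outcome!r}")

    baseline = dataset.baseline
    centers = dict(spec.centers or {})
    for cov in spec.covariates:
        if cov in CONTINUOUS_COLUMNS and cov not in centers:
            centers[cov] = float(baseline[cov].astype(float).mean())

    mains_all, names = encode_mains(baseline, spec.covariates, centers)
    ids = baseline["participant_id"].tolist()
    pos = {pid: i for i, pid in enumerate(ids)}
    pidx = rec["participant_id"].map(pos).to_numpy(int)

    t = (rec["timepoint"] == "6mo").to_numpy(float)
    g = rec["group"].to_numpy(float)
    mains = mains_all[pidx]
    X = np.concatenate(
        [
            np.column_stack([np.ones(len(rec)), t, g, t * g]),
            mains,
            g[:, None] * mains,
        ],
        axis=1,
    )
    columns = (
        ["intercept", "time", "group", "time:group"]
        + names
        + [f"group:{c}" for c in names]
    )
    # a covariate with a single observed level yields a constant column
    sds = X[:, 4 : 4 + len(names)].std(axis=0)
    if len(names) and (sds == 0).any():
        bad = names[int(np.argmin(sds))]
        raise DegenerateDesignError(
            f"covariate column {bad!r} is constant in the observed data"
        )
    y = rec["value"].to_numpy(float)
    return Design(
        X=X,
        y=y,
        columns=columns,
        participant_index=pidx,
        participant_ids=ids,
        centers=centers,
        covariates=list(spec.covariates),
        outcome=outcome,
        idx_mains=slice(4, 4 + len(names)),
        idx_interactions=slice(4 + len(names), 4 + 2 * len(names)),
    )
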