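"""Trial data containers and CSV round-trip.

A trial is stored as a wide baseline table (one row per participant), an
allocation map (participant -> arm), and a long outcome table with one row
per participant x timepoint x outcome.  Missing outcome values (participant
did not respond at that follow-up) are empty cells / NaN.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset",
    "SchemaError",
    "CATEGORICAL_LEVELS",
    "FLAG_COLUMNS",
    "CONTINUOUS_COLUMNS",
    "SCORE_BOUNDS",
    "BASELINE_COLUMNS",
    "OUTCOMES",
    "TIMEPOINTS",
    "read_trial_csv",
    "write_trial_csv",
]

#: Enumerated levels per categorical covariate; the first level is the
#: reference used for dummy coding (woman, snus daily, counseling "no",
#: primary-care recruitment).
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "gender": ["woman", "man"],
    "snus_use": ["daily", "weekly_or_monthly", "none"],
    "counseling": ["no", "yes_past", "yes_now"],
    "setting": ["primary_care", "online"],
}

FLAG_COLUMNS = ["daily_smoker", "used_quitline", "elective_surgery"]

CONTINUOUS_COLUMNS = [
    "age",
    "years_smoking",
    "cigarettes_per_week",
    "fagerstrom",
    "quit_attempts",
    "importance",
    "confidence",
    "knowhow",
]

#: Hard range constraints checked during validation.
SCORE_BOUNDS: dict[str, tuple[float, float]] = {
    "importance": (0.0, 10.0),
    "confidence": (0.0, 10.0),
    "knowhow": (0.0, 10.0),
    "fagerstrom": (0.0, 10.0),
}

BASELINE_COLUMNS = (
    ["participant_id"]
    + list(CATEGORICAL_LEVELS)
    + FLAG_COLUMNS
    + CONTINUOUS_COLUMNS
)

OUTCOMES = ["prolonged", "point_prevalence"]
TIMEPOINTS = ["3mo", "6mo"]


class SchemaError(ValueError):
    """A trial table violates the declared schema (named row/column)."""


@dataclasses.dataclass
class TrialDataset:
    """Baseline covariates, arm allocation, and long-format outcomes.

    Parameters
    ----------
    baseline : DataFrame
        One row per participant with the columns in :data:`BASELINE_COLUMNS`.
    allocation : Series
        Indexed by participant_id, values in {0 (control), 1 (intervention)}.
    outcomes : DataFrame
        Columns participant_id, timepoint, outcome, value; value is 0/1 or
        NaN for a missed follow-up.
    """

    baseline: pd.DataFrame
    allocation: pd.Series
    outcomes: pd.DataFrame

    @property
    def n_participants(self) -> int:
        return len(self.baseline)

    def validate(self) -> "TrialDataset":
        """Check schema, ranges, and record completeness; raise SchemaError."""
        missing = [c for c in BASELINE_COLUMNS if c not in self.baseline.columns]
        if missing:
            raise SchemaError(f"baseline table missing columns: {missing}")
        ids = self.baseline["participant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SchemaError(f"duplicate participant_id {dup!r}")
        for col, levels in CATEGORICAL_LEVELS.items():
            bad = ~self.baseline[col].isin(levels)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"unknown category {self.baseline[col].iloc[row]!r} in "
                    f"column {col!r} at row {row} (allowed: {levels})"
                )
        for col in FLAG_COLUMNS:
            vals = self.baseline[col]
            if not vals.isin([0, 1, True, False]).all():
                row = int(np.flatnonzero(~vals.isin([0, 1, True, False]))[0])
                raise SchemaError(f"non-boolean value in {col!r} at row {row}")
        for col, (lo, hi) in SCORE_BOUNDS.items():
            vals = self.baseline[col].astype(float)
            bad = (vals < lo) | (vals > hi)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"value {vals.iloc[row]} out of range [{lo}, {hi}] in "
                    f"column {col!r} at row {row}"
                )
        for col in CONTINUOUS_COLUMNS:
            vals = self.baseline[col].astype(float)
            if not np.isfinite(vals).all():
                row = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise SchemaError(f"non-finite value in {col!r} at row {row}")
        neg = self.baseline["years_smoking"].astype(float) >= self.baseline[
            "age"
        ].astype(float)
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise SchemaError(
                f"years_smoking >= age at row {row} "
                f"(participant {ids.iloc[row]!r})"
            )

        if not set(ids) <= set(self.allocation.index):
            lost = sorted(set(ids) - set(self.allocation.index))[:3]
            raise SchemaError(f"participants without allocation: {lost} ...")
        if not self.allocation.isin([0, 1]).all():
            raise SchemaError("allocation values must be 0 or 1")

        oc = self.outcomes
        for col in ("participant_id", "timepoint", "outcome", "value"):
            if col not in oc.columns:
                raise SchemaError(f"outcomes table missing column {col!r}")
        if len(oc):
            if not oc["timepoint"].isin(TIMEPOINTS).all():
                raise SchemaError(f"timepoint values must be in {TIMEPOINTS}")
            if not oc["outcome"].isin(OUTCOMES).all():
                raise SchemaError(f"outcome values must be in {OUTCOMES}")
            vals = oc["value"].astype(float)
            if not (vals.isna() | vals.isin([0.0, 1.0])).all():
                row = int(np.flatnonzero((~(vals.isna() | vals.isin([0.0, 1.0]))).to_numpy())[0])
                raise SchemaError(f"outcome value not in {{0, 1, missing}} at row {row}")
            counts = oc.groupby(["participant_id", "timepoint", "outcome"]).size()
            if (counts != 1).any():
                key = counts[counts != 1].index[0]
                raise SchemaError(f"duplicate outcome record for {key}")
            # every participant has exactly one record per timepoint x outcome
            # (over the outcomes the table actually carries)
            expected = len(ids) * len(TIMEPOINTS) * oc["outcome"].nunique()
            covered = oc["participant_id"].isin(ids)
            if not covered.all():
                stray = oc.loc[~covered, "participant_id"].iloc[0]
                raise SchemaError(f"outcome record for unknown participant {stray!r}")
            if len(oc) != expected:
                raise SchemaError(
                    f"outcomes table has {len(oc)} records, expected {expected} "
                    "(one per participant x timepoint x outcome)"
                )
        elif len(ids):
            raise SchemaError("outcomes table is empty but participants exist")
        return self

    def observed(self, outcome: str) -> pd.DataFrame:
        """Non-missing records of one outcome, merged with arm and baseline."""
        if outcome not in OUTCOMES:
            raise SchemaError(f"unknown outcome {outcome!r} (allowed: {OUTCOMES})")
        rec = self.outcomes[self.outcomes["outcome"] == outcome]
        rec = rec[rec["value"].notna()].copy()
        rec["group"] = rec["participant_id"].map(self.allocation).astype(int)
        return rec


def write_trial_csv(dataset: TrialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write baseline/allocation/outcomes CSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "baseline": out / "baseline.csv",
        "allocation": out / "allocation.csv",
        "outcomes": out / "outcomes.csv",
    }
    baseline = dataset.baseline.copy()
    for col in FLAG_COLUMNS:
        baseline[col] = baseline[col].astype(int)
    baseline.to_csv(paths["baseline"], index=False)
    dataset.allocation.rename("group").rename_axis("participant_id").to_csv(
        paths["allocation"]
    )
    oc = dataset.outcomes.copy()
    oc["group"] = oc["participant_id"].map(dataset.allocation).astype(int)
    oc[["participant_id", "timepoint", "group", "outcome", "value"]].to_csv(
        paths["outcomes"], index=False
    )
    return paths


def read_trial_csv(in_dir: str | Path) -> TrialDataset:
    """Read a trial written by :func:`write_trial_csv` and validate it."""
    p = Path(in_dir)
    baseline = pd.read_csv(p / "baseline.csv")
    for col in FLAG_COLUMNS:
        if col in baseline.columns:
            baseline[col] = baseline[col].astype(bool)
    alloc = pd.read_csv(p / "allocation.csv", index_col="participant_id")["group"]
    outcomes = pd.read_csv(p / "outcomes.csv")
    outcomes = outcomes[["participant_id", "timepoint", "outcome", "value"]]
    ds = TrialDataset(baseline=baseline, allocation=alloc, outcomes=outcomes)
    return ds.validate()
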