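"""Cohort tables, cumulative-interval discretization and prevalence filtering.

The analysis operates on first-onset disease histories: one row per
(participant, three-character ICD-10 category) giving the age at first onset,
plus a covariate table with a right-censoring age per participant.  Onset ages
are discretized onto *cumulative* age intervals [0, e_1], ..., [0, e_T]
(default ends 20, 40, 60, 70 years): the binary indicator for disease d,
participant i, interval t is 1 iff the first onset occurred at or before e_t.
A participant contributes to interval t only when observed through its end,
i.e. censor_age >= e_t, which yields a monotone inclusion mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ONSET_COLUMNS = ["participant_id", "disease_code", "onset_age"]
COVARIATE_COLUMNS = ["participant_id", "sex", "birth_year", "income", "censor_age"]


class CohortValidationError(ValueError):
    """Raised when an onset or covariate table violates cohort invariants."""


@dataclass(frozen=True)
class TimeGrid:
    """Ordered ends of the cumulative age intervals, in years."""

    interval_ends: tuple[float, ...] = (20.0, 40.0, 60.0, 70.0)

    def __post_init__(self) -> None:
        ends = tuple(float(e) for e in self.interval_ends)
        if len(ends) == 0:
            raise ValueError("TimeGrid needs at least one interval end")
        if any(e <= 0 for e in ends) or any(
            b <= a for a, b in zip(ends, ends[1:])
        ):
            raise ValueError("interval ends must be positive and strictly increasing")
        object.__setattr__(self, "interval_ends", ends)

    @property
    def n_intervals(self) -> int:
        return len(self.interval_ends)

    @property
    def band_edges(self) -> tuple[float, ...]:
        """Edges of the disjoint age bands (0, e_1], (e_1, e_2], ..."""
        return (0.0,) + self.interval_ends


@dataclass
class CohortTable:
    """First-onset records plus per-participant covariates.

    ``onsets`` has columns participant_id, disease_code, onset_age (years);
    ``covariates`` has participant_id, sex, birth_year, income, censor_age and
    any additional risk-factor columns.  At most one onset per
    (participant, disease); onset_age never exceeds the participant's
    censor_age.
    """

    onsets: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in ONSET_COLUMNS if c not in self.onsets.columns]
        if missing:
            raise CohortValidationError(f"onset table missing columns {missing}")
        missing = [c for c in COVARIATE_COLUMNS if c not in self.covariates.columns]
        if missing:
            raise CohortValidationError(f"covariate table missing columns {missing}")
        cov = self.covariates
        if cov["participant_id"].duplicated().any():
            raise CohortValidationError("duplicate participant in covariate table")
        if len(self.onsets):
            known = set(cov["participant_id"])
            unknown = set(self.onsets["participant_id"]) - known
            if unknown:
                raise CohortValidationError(
                    f"onset rows reference unknown participants: {sorted(unknown)[:5]}"
                )
            dup = self.onsets.duplicated(["participant_id", "disease_code"])
            if dup.any():
                raise CohortValidationError(
                    "multiple onsets per (participant, disease); keep first onsets only"
                )
            censor = cov.set_index("participant_id")["censor_age"]
            over = self.onsets["onset_age"].to_numpy() > censor.loc[
                self.onsets["participant_id"]
            ].to_numpy()
            if over.any():
                row = self.onsets[over].iloc[0]
                raise CohortValidationError(
                    f"onset after censor age for participant "
                    f"{row['participant_id']!r}, disease {row['disease_code']!r} "
                    f"(onset_age={row['onset_age']})"
                )
            if (self.onsets["onset_age"].to_numpy() < 0).any():
                raise CohortValidationError("negative onset age")

    @property
    def participants(self) -> np.ndarray:
        return self.covariates["participant_id"].to_numpy()

    @property
    def n_participants(self) -> int:
        return len(self.covariates)

    def censor_ages(self) -> pd.Series:
        return self.covariates.set_index("participant_id")["censor_age"]

    def disease_codes(self) -> list[str]:
        return sorted(self.onsets["disease_code"].unique()) if len(self.onsets) else []


@dataclass
class IntervalPanel:
    """Binary cumulative-onset indicators with a censoring-aware inclusion mask.

    ``indicators[i, d, t]`` is 1 iff participant i's first onset of disease d
    occurred at or before ``grid.interval_ends[t]`` (closed right end);
    ``included[i, t]`` is True iff the participant is observed through the
    interval end.  Indicators are meaningful only where ``included`` holds.
    """

    indicators: np.ndarray  # (n_participants, n_diseases, n_intervals) uint8
    included: np.ndarray  # (n_participants, n_intervals) bool
    codes: list[str]
    participants: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        n, d, t = self.indicators.shape
        if self.included.shape != (n, t):
            raise ValueError("included mask shape mismatch")
        if len(self.codes) != d or len(self.participants) != n:
            raise ValueError("codes/participants length mismatch")
        if t != self.grid.n_intervals:
            raise ValueError("grid mismatch")

    def code_index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"disease {code!r} not in panel") from None

    def restrict(self, codes: Sequence[str]) -> "IntervalPanel":
        idx = [self.code_index(c) for c in codes]
        return IntervalPanel(
            indicators=self.indicators[:, idx, :],
            included=self.included,
            codes=list(codes),
            participants=self.participants,
            grid=self.grid,
        )


def read_cohort(onset_path: str | Path, covariate_path: str | Path) -> CohortTable:
    """Read TSV onset and covariate tables into a validated :class:`CohortTable`.

    Duplicate (participant, disease) onset rows are collapsed to the earliest
    onset (first-onset rule); invariant violations raise
    :class:`CohortValidationError`.
    """
    onsets = pd.read_csv(onset_path, sep="\t", dtype={"participant_id": str})
    covariates = pd.read_csv(covariate_path, sep="\t", dtype={"participant_id": str})
    if len(onsets):
        onsets = (
            onsets.sort_values("onset_age", kind="stable")
            .drop_duplicates(["participant_id", "disease_code"], keep="first")
            .reset_index(drop=True)
        )
    else:
        onsets = pd.DataFrame(columns=ONSET_COLUMNS)
    return CohortTable(onsets=onsets, covariates=covariates)


def write_cohort(
    cohort: CohortTable, onset_path: str | Path, covariate_path: str | Path
) -> None:
    cohort.onsets.to_csv(onset_path, sep="\t", index=False)
    cohort.covariates.to_csv(covariate_path, sep="\t", index=False)


def discretize(cohort: CohortTable, grid: TimeGrid | None = None) -> IntervalPanel:
    """Discretize first onsets to cumulative-interval indicators.

    ``indicator[i, d, t] = 1`` iff onset_age(i, d) <= interval_ends[t]
    (onsets falling exactly on an interval end count as inside);
    ``included[i, t] = censor_age(i) >= interval_ends[t]``.
    """
    grid = grid or TimeGrid()
    ends = np.asarray(grid.interval_ends)
    participants = cohort.participants
    codes = cohort.disease_codes()
    n, d, t = len(participants), len(codes), grid.n_intervals
    indicators = np.zeros((n, d, t), dtype=np.uint8)
    if len(cohort.onsets):
        pidx = pd.Series(np.arange(n), index=participants)
        didx = pd.Series(np.arange(d), index=codes)
        rows = pidx.loc[cohort.onsets["participant_id"]].to_numpy()
        cols = didx.loc[cohort.onsets["disease_code"]].to_numpy()
        ages = cohort.onsets["onset_age"].to_numpy()
        indicators[rows[:, None], cols[:, None], np.arange(t)[None, :]] = (
            ages[:, None] <= ends[None, :]
        ).astype(np.uint8)
    censor = cohort.covariates["censor_age"].to_numpy()
    included = censor[:, None] >= ends[None, :]
    return IntervalPanel(
        indicators=indicators,
        included=included,
        codes=codes,
        participants=participants,
        grid=grid,
    )


def prevalence_filter(
    cohort: CohortTable,
    threshold: float = 0.01,
    target_codes: Iterable[str] = (),
) -> list[str]:
    """Diseases with prevalence strictly above ``threshold`` in the whole cohort
    OR among participants carrying any target code; target codes are always
    retained (when present in the cohort)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    target_codes = set(target_codes)
    if not target_codes:
        raise ValueError("target_codes must be non-empty")
    if cohort.n_participants == 0:
        raise CohortValidationError("cannot compute prevalence on an empty cohort")
    onsets = cohort.onsets
    counts = onsets.groupby("disease_code")["participant_id"].nunique()
    prev_all = counts / cohort.n_participants
    carriers = set(
        onsets.loc[onsets["disease_code"].isin(target_codes), "participant_id"]
    )
    keep = set(prev_all.index[prev_all > threshold])
    if carriers:
        sub = onsets[onsets["participant_id"].isin(carriers)]
        sub_counts = sub.groupby("disease_code")["participant_id"].nunique()
        prev_sub = sub_counts / len(carriers)
        keep |= set(prev_sub.index[prev_sub > threshold])
    keep |= target_codes & set(counts.index)
    return sorted(keep)
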