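"""Reference standards and dataset construction.

An exam is a *case* under a follow-up window of ``w`` months when its
participant is diagnosed between 0 and ``w`` months (inclusive on both ends)
after the exam; every other exam is a *control*.  Because healthy status can
only be confirmed for exams acquired at least ``w`` months before the end of
data collection, all exams after that cutoff are excluded from labelling.

Two dataset shapes are supported, mirroring screening-program evaluation
practice:

* a *cohort*: every labelled exam of one calendar year, at true prevalence;
* a *case-control* selection: per screening year in descending order, all
  case participants with a case exam that year, plus randomly drawn healthy
  control participants at a fixed ratio (default 1:5), one most-recent exam
  each; selected participants are removed from the pool before earlier years
  are processed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .synthgen import month_index, score_columns

__all__ = [
    "FollowUpWindow",
    "LabeledDataset",
    "DataIntegrityError",
    "ControlShortfallError",
    "label_exams",
    "build_cohort",
    "build_case_control",
]

WINDOW_PRESETS = (12, 24, 36, 48)


class DataIntegrityError(ValueError):
    """A diagnosis date precedes the participant's first exam."""


class ControlShortfallError(RuntimeError):
    """A screening year has fewer available healthy controls than the ratio
    requires."""

    def __init__(self, year: int, needed: int, available: int):
        self.year, self.needed, self.available = year, needed, available
        super().__init__(
            f"screening year {year}: need {needed} controls, only {available} available; "
            f"reduce the ratio or enlarge the population"
        )


@dataclass(frozen=True)
class FollowUpWindow:
    """Follow-up period (months) defining the reference standard."""

    months: int = 36

    def __post_init__(self):
        if self.months <= 0:
            raise ValueError(f"window must be positive, got {self.months}")


@dataclass
class LabeledDataset:
    """Exam set plus case/control labels under one follow-up window.

    ``labels`` is a Series indexed by exam_id with values 'case'/'control',
    aligned to ``exams`` row order.
    """

    exams: pd.DataFrame
    labels: pd.Series
    window: FollowUpWindow
    provenance: str = ""

    def __post_init__(self):
        if len(self.labels) != len(self.exams):
            raise ValueError("labels must cover every exam exactly once")
        if not (self.labels.index == self.exams["exam_id"].to_numpy()).all():
            self.labels = self.labels.reindex(self.exams["exam_id"])
            if self.labels.isna().any():
                raise ValueError("labels must cover every exam exactly once")

    # -- convenience accessors ------------------------------------------------

    @property
    def n_exams(self) -> int:
        return len(self.exams)

    @property
    def case_mask(self) -> np.ndarray:
        return (self.labels.to_numpy() == "case")

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return self.n_exams - self.n_cases

    def scores(self, ai_system: str) -> np.ndarray:
        return self.exams[f"score_{ai_system}"].to_numpy(dtype=float)

    @property
    def ai_systems(self) -> list[str]:
        return [c[len("score_"):] for c in score_columns(self.exams)]

    @property
    def participants(self) -> pd.Series:
        return self.exams["participant_id"]

    def subset(self, mask: np.ndarray, provenance: str | None = None) -> "LabeledDataset":
        exams = self.exams[mask].reset_index(drop=True)
        labels = self.labels[np.asarray(mask)]
        return LabeledDataset(exams, labels, self.window, provenance or self.provenance)

    def to_frame(self) -> pd.DataFrame:
        out = self.exams.copy()
        out["label"] = self.labels.to_numpy()
        return out

    def save(self, path: str | Path) -> None:
        """Write the labelled table (added ``label`` column) plus a JSON
        provenance sidecar."""
        from .synthgen import write_exams

        path = Path(path)
        write_exams(self.to_frame(), path)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(
            json.dumps(
                {
                    "window_months": self.window.months,
                    "provenance": self.provenance,
                    "n_exams": self.n_exams,
                    "n_cases": self.n_cases,
                    "n_controls": self.n_controls,
                },
                indent=2,
            )
        )


def _months_to_dx(exams: pd.DataFrame) -> np.ndarray:
    """Whole months from exam to diagnosis (NaN when never diagnosed)."""
    dx = month_index(
        exams["diagnosis_year"].astype("float"), exams["diagnosis_month"].astype("float")
    )
    return np.asarray(dx - month_index(exams["exam_year"], exams["exam_month"]), dtype=float)


def label_exams(
    exams: pd.DataFrame,
    window: FollowUpWindow | int = FollowUpWindow(),
    *,
    collection_end: tuple[int, int] | None = None,
    integrity_tolerance_months: int = 1,
) -> LabeledDataset:
    """Apply the reference standard at the given follow-up window.

    Exams dated later than ``collection_end - window`` are excluded, since a
    healthy outcome cannot be confirmed for them (the registry records end at
    ``collection_end``, defaulting to the latest exam date in the table).
    """
    if isinstance(window, int):
        window = FollowUpWindow(window)
    t = month_index(exams["exam_year"], exams["exam_month"]).astype(np.int64)
    if collection_end is None:
        end_t = int(t.max())
    else:
        end_t = int(month_index(collection_end[0], collection_end[1]))

    m2d = _months_to_dx(exams)
    first_t = pd.Series(t, index=exams.index).groupby(exams["participant_id"]).transform("min")
    early = m2d < -(integrity_tolerance_months)
    bad = early & (t == first_t)
    if bad.any():
        who = exams.loc[bad, "participant_id"].unique()[:5]
        raise DataIntegrityError(
            f"diagnosis precedes first exam for participant(s) {list(who)}"
        )

    keep = t <= end_t - window.months
    kept = exams[keep].reset_index(drop=True)
    m2d = m2d[np.asarray(keep)]
    is_case = np.nan_to_num(m2d, nan=-1.0) >= 0
    is_case &= m2d <= window.months
    labels = pd.Series(
        np.where(is_case, "case", "control"), index=kept["exam_id"], name="label"
    )
    prov = (
        f"label_exams(window={window.months}m, collection_end_month={end_t}, "
        f"excluded={int((~keep).sum())})"
    )
    return LabeledDataset(kept, labels, window, prov)


def build_cohort(
    exams: pd.DataFrame,
    year: int,
    window: FollowUpWindow | int = FollowUpWindow(),
    *,
    collection_end: tuple[int, int] | None = None,
) -> LabeledDataset:
    """All labelled exams of one calendar year, no sampling (true prevalence)."""
    labeled = label_exams(exams, window, collection_end=collection_end)
    mask = (labeled.exams["exam_year"] == year).to_numpy()
    if not mask.any():
        warnings.warn(f"cohort year {year}: no labelled exams", stacklevel=2)
    return labeled.subset(mask, provenance=f"cohort(year={year}, window={labeled.window.months}m)")


def build_case_control(
    exams: pd.DataFrame,
    window: FollowUpWindow | int = FollowUpWindow(),
    ratio: int = 5,
    seed: int = 0,
    *,
    collection_end: tuple[int, int] | None = None,
) -> LabeledDataset:
    """Per-year case-control selection at ``ratio`` healthy control
    participants per case participant.

    Processing screening years in descending order: case participants with a
    case-labelled exam in the year are taken with *all* their case exams;
    ``ratio`` times as many healthy participants (never diagnosed) with an
    exam that year are drawn at random, contributing their most recent
    labelled exam up to that year (ties broken by exam_id).  Selected
    participants leave the pool before earlier years are processed.  The
    case set is deterministic; only the control draw depends on ``seed``.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    labeled = label_exams(exams, window, collection_end=collection_end)
    df = labeled.to_frame()
    df["t"] = month_index(df["exam_year"], df["exam_month"])
    diagnosed = df.groupby("participant_id")["diagnosis_year"].first().notna()
    healthy_ids = set(diagnosed.index[~diagnosed])

    rng = np.random.default_rng(seed)
    case_rows: list[pd.DataFrame] = []
    control_rows: list[pd.DataFrame] = []
    taken: set[str] = set()

    years = sorted(df["exam_year"].unique(), reverse=True)
    for year in years:
        in_year = df[df["exam_year"] == year]
        case_pids = sorted(
            set(in_year.loc[in_year["label"] == "case", "participant_id"]) - taken
        )
        if case_pids:
            case_exams = df[(df["participant_id"].isin(case_pids)) & (df["label"] == "case")]
            case_rows.append(case_exams)
        need = ratio * len(case_pids)
        pool = sorted(
            (set(in_year["participant_id"]) & healthy_ids) - taken
        )
        if need > 0:
            if len(pool) < need:
                raise ControlShortfallError(int(year), need, len(pool))
            chosen = rng.choice(np.asarray(pool, dtype=object), size=need, replace=False)
            candidates = df[
                df["participant_id"].isin(chosen) & (df["exam_year"] <= year)
            ].sort_values(["participant_id", "t", "exam_id"])
            most_recent = candidates.groupby("participant_id", sort=True).tail(1)
            control_rows.append(most_recent)
            taken.update(chosen.tolist())
        taken.update(case_pids)

    parts = [p for p in case_rows + control_rows if len(p)]
    if not parts:
        selected = df.iloc[0:0]
    else:
        selected = pd.concat(parts, axis=0)
    selected = selected.sort_values(["participant_id", "t", "exam_id"]).reset_index(drop=True)
    labels = pd.Series(
        selected["label"].to_numpy(), index=selected["exam_id"], name="label"
    )
    exams_out = selected.drop(columns=["label", "t"])
    prov = (
        f"case_control(window={labeled.window.months}m, ratio=1:{ratio}, seed={seed}, "
        f"years={years[-1] if years else None}-{years[0] if years else None} descending)"
    )
    return LabeledDataset(exams_out, labels, labeled.window, prov)
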