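"""Synthetic mammography-screening populations.

Generates longitudinal exam-level records for a biennial screening program:
participants enter at a random point of the study window, are screened every
``screening_interval_months`` while inside the eligible age range, and may
develop a breast cancer that surfaces at a screening round and is diagnosed
a short, variable lag later.  Each exam carries a consensus double-reading
recall decision and one continuous malignancy score per simulated AI system.

The score model is an equal-variance binormal latent per class, shifted
additively per vendor, density category, age band and cancer type, and
squashed to [0, 1] by the logistic function.  Because the logistic map is
strictly monotone, the ROC of each system has the closed form
``AUC = Phi(delta / (sigma * sqrt(2)))`` when all subgroup shifts are zero,
which the tests use as an independent oracle.

Exams of a diagnosed participant draw from the case latent only while inside
a configurable detectability horizon (default 36 months before diagnosis);
earlier exams are radiologically normal and draw from the control latent.
The radiologist recall probability for pre-diagnosis exams is a decreasing
piecewise-linear function of months-to-diagnosis, which reproduces the
short-follow-up advantage of readers over AI.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "AGE_BANDS",
    "DENSITY_CATEGORIES",
    "EXAM_COLUMNS",
    "PopulationConfig",
    "ReaderConfig",
    "AISystemConfig",
    "ScoreModelConfig",
    "ExamRecord",
    "EmptyPopulationError",
    "generate_population",
    "summarize_population",
    "matched_case_mean",
    "default_population_config",
    "default_score_config",
    "score_columns",
    "validate_exam_frame",
    "write_exams",
    "read_exams",
]

DENSITY_CATEGORIES = ("A", "B", "C", "D")
#: Age bands used for stratified reporting and band-dependent parameters.
AGE_BANDS = ("40-49", "50-69", "70+")

PROB_TOL = 1e-9

#: Fixed column order of the exam table written by :func:`write_exams`.
#: ``score_<system>`` columns are inserted between ``radiologist_recall``
#: and ``diagnosis_year`` in sorted system order.
EXAM_COLUMNS = (
    "exam_id",
    "participant_id",
    "exam_year",
    "exam_month",
    "age_at_exam",
    "density",
    "vendor",
    "region",
    "radiologist_recall",
    # score_<system>...
    "diagnosis_year",
    "diagnosis_month",
    "cancer_type",
)


class EmptyPopulationError(ValueError):
    """Raised when a configuration cannot produce any examination."""


def age_band(age) -> np.ndarray:
    """Map integer ages to the reporting bands 40-49 / 50-69 / 70+."""
    age = np.asarray(age)
    out = np.where(age >= 70, "70+", np.where(age >= 50, "50-69", "40-49"))
    return out


def month_index(year, month) -> np.ndarray:
    """Serial month number (January of year 0 = 0).  All date arithmetic in
    this package is month-granular."""
    return np.asarray(year) * 12 + (np.asarray(month) - 1)


def _check_prob_vector(probs: Mapping[str, float], keys: Sequence[str], name: str) -> None:
    missing = set(keys) - set(probs)
    if missing:
        raise ValueError(f"{name}: missing categories {sorted(missing)}")
    total = float(sum(probs.values()))
    if abs(total - 1.0) > PROB_TOL:
        raise ValueError(f"{name}: probabilities sum to {total!r}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name}: negative probability")


class PopulationConfig(BaseModel):
    """Demographic / longitudinal structure of the simulated program.

    ``incidence_per_round`` is the probability that a cancer surfaces at a
    given screening round, either a scalar or a map over age bands.  It is
    multiplied by ``incidence_density_rr`` (relative risk per density
    category), which lets the generator reproduce the empirical pattern that
    cancer cases are simultaneously older *and* denser-breasted than
    controls even though density itself declines with age.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_participants: int = Field(gt=0)
    year_range: tuple[int, int] = (2008, 2021)
    age_range: tuple[int, int] = (40, 74)
    screening_interval_months: int = Field(default=24, gt=0)
    incidence_per_round: float | dict[str, float] = Field(
        default_factory=lambda: {"40-49": 0.007, "50-69": 0.012, "70+": 0.016}
    )
    incidence_density_rr: dict[str, float] = Field(
        default_factory=lambda: {"A": 0.5, "B": 0.8, "C": 1.4, "D": 2.2}
    )
    vendor_mix_by_year: dict[int, dict[str, float]] | None = None
    density_given_age: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "40-49": {"A": 0.05, "B": 0.35, "C": 0.45, "D": 0.15},
            "50-69": {"A": 0.12, "B": 0.52, "C": 0.30, "D": 0.06},
            "70+": {"A": 0.22, "B": 0.58, "C": 0.18, "D": 0.02},
        }
    )
    in_situ_fraction: float = Field(default=0.133, ge=0.0, le=1.0)
    diagnosis_lag_max_months: int = Field(default=23, ge=0)
    regions: tuple[str, ...] = ("R1", "R2", "R3")
    seed: int = 0

    @field_validator("year_range", "age_range")
    @classmethod
    def _ordered_range(cls, v):
        if v[1] < v[0]:
            raise ValueError(f"empty range {v}")
        return v

    @model_validator(mode="after")
    def _validate_tables(self):
        if isinstance(self.incidence_per_round, dict):
            for band in AGE_BANDS:
                if band not in self.incidence_per_round:
                    raise ValueError(f"incidence_per_round: missing age band {band!r}")
            rates = self.incidence_per_round.values()
        else:
            rates = [self.incidence_per_round]
        for r in rates:
            if not 0.0 < r < 1.0:
                raise ValueError(f"incidence_per_round: rate {r} outside (0, 1)")
        for band in AGE_BANDS:
            if band not in self.density_given_age:
                raise ValueError(f"density_given_age: missing age band {band!r}")
            _check_prob_vector(
                self.density_given_age[band], DENSITY_CATEGORIES, f"density_given_age[{band}]"
            )
        for cat in DENSITY_CATEGORIES:
            if cat not in self.incidence_density_rr:
                raise ValueError(f"incidence_density_rr: missing density {cat!r}")
        if self.vendor_mix_by_year is not None:
            for year in range(self.year_range[0], self.year_range[1] + 1):
                if year not in self.vendor_mix_by_year:
                    raise ValueError(f"vendor_mix_by_year: missing year {year}")
                mix = self.vendor_mix_by_year[year]
                _check_prob_vector(mix, list(mix), f"vendor_mix_by_year[{year}]")
        return self

    def incidence(self, band: str) -> float:
        if isinstance(self.incidence_per_round, dict):
            return self.incidence_per_round[band]
        return self.incidence_per_round

    def vendor_mix(self) -> dict[int, dict[str, float]]:
        """Vendor mix per year; default drifts from GE-dominated to a
        Philips-heavy mix over the study window (the temporal confounder)."""
        if self.vendor_mix_by_year is not None:
            return self.vendor_mix_by_year
        y0, y1 = self.year_range
        span = max(y1 - y0, 1)
        out = {}
        for year in range(y0, y1 + 1):
            ge = 0.85 - 0.40 * (year - y0) / span
            out[year] = {"GE": round(ge, 6), "Philips": round(1.0 - ge, 6)}
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "PopulationConfig":
        with open(path) as fh:
            data = json.load(fh)
        # JSON objects force string keys; restore the typed ones.
        if "vendor_mix_by_year" in data and data["vendor_mix_by_year"] is not None:
            data["vendor_mix_by_year"] = {
                int(k): v for k, v in data["vendor_mix_by_year"].items()
            }
        return cls.model_validate(data)


class ReaderConfig(BaseModel):
    """Radiologist double-reading consensus model.

    Recall for healthy exams is ``1 - specificity``.  Recall for a
    pre-diagnosis exam of a diagnosed participant decreases piecewise
    linearly with months-to-diagnosis:
    ``r(m) = clip(recall_at_diagnosis - slope * m, floor, 1)`` with the
    floor defaulting to the healthy recall rate.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    specificity: float = Field(default=0.93, gt=0.0, lt=1.0)
    recall_at_diagnosis: float = Field(default=0.95, ge=0.0, le=1.0)
    recall_slope_per_month: float = Field(default=0.02, ge=0.0)
    recall_floor: float | None = None
    ai_correlation: float = Field(default=0.3, ge=0.0, lt=1.0)

    def case_recall(self, months_to_dx) -> np.ndarray:
        floor = self.recall_floor if self.recall_floor is not None else 1.0 - self.specificity
        m = np.asarray(months_to_dx, dtype=float)
        return np.clip(self.recall_at_diagnosis - self.recall_slope_per_month * m, floor, 1.0)


def _as_class_shift(v) -> tuple[float, float]:
    """Normalize a shift entry to a (control, case) pair.

    A scalar shifts both classes (pure location effect); a pair expresses a
    class-asymmetric effect, i.e. a separation change, which is what an
    'AI performs better on vendor X' finding requires.
    """
    if isinstance(v, (int, float)):
        return (float(v), float(v))
    ctrl, case = v
    return (float(ctrl), float(case))


class AISystemConfig(BaseModel):
    """Latent score model for one AI system.

    Latent = class mean + subgroup shifts + sd * noise; score = logistic(latent).
    Shift maps give (control, case) latent offsets per category; a bare float
    is broadcast to both classes.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    control_mean: float = 0.0
    case_mean: float = 1.703
    control_sd: float = Field(default=1.0, gt=0.0)
    case_sd: float = Field(default=1.0, gt=0.0)
    vendor_shift: dict[str, tuple[float, float]] = Field(default_factory=dict)
    density_shift: dict[str, tuple[float, float]] = Field(default_factory=dict)
    age_shift: dict[str, tuple[float, float]] = Field(default_factory=dict)
    cancer_type_shift: dict[str, float] = Field(default_factory=dict)

    @field_validator("vendor_shift", "density_shift", "age_shift", mode="before")
    @classmethod
    def _norm_shifts(cls, v):
        if v is None:
            return {}
        return {k: _as_class_shift(s) for k, s in v.items()}

    def shift_for(self, table: str, key: str, is_case: bool) -> float:
        shifts = getattr(self, table)
        if key not in shifts:
            return 0.0
        return shifts[key][1 if is_case else 0]


class ScoreModelConfig(BaseModel):
    """Score models for all AI systems plus the shared reader model."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    systems: dict[str, AISystemConfig]
    reader: ReaderConfig = Field(default_factory=ReaderConfig)
    detectability_horizon_months: int = Field(default=36, gt=0)

    @model_validator(mode="after")
    def _nonempty(self):
        if not self.systems:
            raise ValueError("systems: at least one AI system required")
        return self

    def check_covers(self, population: PopulationConfig) -> None:
        """Verify every shift map covers only categories the population emits
        (unknown keys are silently inert otherwise, which hides typos)."""
        vendors = set()
        for mix in population.vendor_mix().values():
            vendors |= set(mix)
        for name, sys_cfg in self.systems.items():
            for key in sys_cfg.vendor_shift:
                if key not in vendors:
                    raise ValueError(f"systems[{name}].vendor_shift: unknown vendor {key!r}")
            for key in sys_cfg.density_shift:
                if key not in DENSITY_CATEGORIES:
                    raise ValueError(f"systems[{name}].density_shift: unknown density {key!r}")
            for key in sys_cfg.age_shift:
                if key not in AGE_BANDS:
                    raise ValueError(f"systems[{name}].age_shift: unknown age band {key!r}")
            for key in sys_cfg.cancer_type_shift:
                if key not in ("invasive", "in_situ"):
                    raise ValueError(
                        f"systems[{name}].cancer_type_shift: unknown type {key!r}"
                    )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreModelConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def matched_case_mean(
    reader: ReaderConfig | None = None, *, window_months: int = 36, control_mean: float = 0.0,
    sd: float = 1.0,
) -> float:
    """Base case-latent mean that puts the AI on the reader's operating point
    at the given follow-up window.

    With a uniform diagnosis lag over one screening interval, every
    months-to-diagnosis value ``m = 0..w`` is (to edge effects) equally
    represented among case exams, so the expected reader sensitivity at
    window ``w`` is ``mean(r(m), m=0..w)``.  The AI true-positive rate at the
    reader's false-positive rate ``f`` is ``Phi(delta/sd - z_{1-f})``; setting
    the two equal gives ``delta = sd * (z_{1-f} + Phi^-1(S(w)))``.
    """
    reader = reader or ReaderConfig()
    m = np.arange(window_months + 1)
    s_w = float(np.mean(reader.case_recall(m)))
    delta = sd * (norm.ppf(reader.specificity) + norm.ppf(s_w))
    return control_mean + delta


def default_population_config(n_participants: int = 20_000, seed: int = 0) -> PopulationConfig:
    return PopulationConfig(n_participants=n_participants, seed=seed)


def default_score_config(
    n_systems: int = 3,
    *,
    subgroup_shifts: bool | Sequence[str] = True,
) -> ScoreModelConfig:
    """Three AI systems sharing the reader-matched base separation.

    Subgroup shifts encode the qualitative mechanisms of the study setting:
    GE images score higher in location for both classes while Philips
    separates better (AI AUC higher on Philips); AI discrimination improves
    with age and degrades with density (masking); in-situ cancers score
    lower.  Systems differ by a scale factor on all shifts, so they react
    with different magnitude but common direction, like a panel of
    commercial systems.  ``subgroup_shifts`` may be False (base binormal and
    reader model only -- the configuration that studies the follow-up-window
    reader bias in isolation) or a subset of
    {'vendor', 'density', 'age', 'cancer_type'} for single-mechanism
    experiments.
    """
    if subgroup_shifts is True:
        mechanisms = {"vendor", "density", "age", "cancer_type"}
    elif subgroup_shifts is False:
        mechanisms = set()
    else:
        mechanisms = set(subgroup_shifts)
    reader = ReaderConfig()
    case_mean = matched_case_mean(reader)
    systems: dict[str, AISystemConfig] = {}
    scales = [0.8, 1.0, 1.2]
    for i in range(n_systems):
        s = scales[i % len(scales)]
        kwargs = {}
        if "vendor" in mechanisms:
            kwargs["vendor_shift"] = {
                "GE": (0.4 * s, 0.4 * s),
                "Philips": (-0.2 * s, 0.6 * s),
            }
        if "density" in mechanisms:
            kwargs["density_shift"] = {
                "A": (-0.2 * s, 0.2 * s),
                "B": (0.0, 0.0),
                "C": (0.15 * s, -0.2 * s),
                "D": (0.3 * s, -0.45 * s),
            }
        if "age" in mechanisms:
            kwargs["age_shift"] = {
                "40-49": (0.15 * s, -0.25 * s),
                "50-69": (0.0, 0.0),
                "70+": (-0.15 * s, 0.25 * s),
            }
        if "cancer_type" in mechanisms:
            kwargs["cancer_type_shift"] = {"invasive": 0.0, "in_situ": -0.4 * s}
        systems[f"ai_{i + 1}"] = AISystemConfig(case_mean=case_mean, **kwargs)
    return ScoreModelConfig(systems=systems, reader=reader)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _categorical(rng_u: np.ndarray, prob_rows: np.ndarray, categories: Sequence[str]) -> np.ndarray:
    """Row-wise categorical draw from per-row probability vectors using
    pre-drawn uniforms (keeps the draw order, hence determinism, explicit)."""
    cum = np.cumsum(prob_rows, axis=1)
    idx = (rng_u[:, None] >= cum).sum(axis=1)
    return np.asarray(categories, dtype=object)[idx]


def generate_population(
    config: PopulationConfig, score_config: ScoreModelConfig
) -> pd.DataFrame:
    """Simulate a screening population and return the exam table.

    Deterministic for a fixed ``config.seed``: two calls with identical
    configurations produce identical tables.
    """
    score_config.check_covers(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    y0, y1 = config.year_range
    a0, a1 = config.age_range
    start_t, end_t = y0 * 12, y1 * 12 + 11
    interval = config.screening_interval_months

    first_t = rng.integers(start_t, end_t + 1, size=n)
    age_first = rng.integers(a0, a1 + 1, size=n)
    region = rng.choice(np.asarray(config.regions, dtype=object), size=n)

    max_rounds = (end_t - start_t) // interval + 1
    k = np.arange(max_rounds)
    t = first_t[:, None] + k[None, :] * interval          # (n, R) exam month index
    age = age_first[:, None] + (k[None, :] * interval) // 12
    valid = (t <= end_t) & (age <= a1)
    if not valid.any():
        raise EmptyPopulationError("configuration yields no examinations")

    pid_idx, round_idx = np.nonzero(valid)
    order = np.lexsort((round_idx, pid_idx))              # participant-major, round order
    pid_idx, round_idx = pid_idx[order], round_idx[order]
    t_e = t[pid_idx, round_idx]
    age_e = age[pid_idx, round_idx].astype(np.int64)
    band_e = age_band(age_e)
    year_e = t_e // 12
    month_e = t_e % 12 + 1

    # density per exam, conditional on current age band
    band_codes = {b: i for i, b in enumerate(AGE_BANDS)}
    dens_probs = np.array(
        [[config.density_given_age[b][c] for c in DENSITY_CATEGORIES] for b in AGE_BANDS]
    )
    band_i = np.vectorize(band_codes.__getitem__)(band_e)
    density_e = _categorical(rng.random(len(t_e)), dens_probs[band_i], DENSITY_CATEGORIES)

    # vendor per exam, by calendar year
    mix = config.vendor_mix()
    vendors = sorted({v for m in mix.values() for v in m})
    vend_probs_by_year = {
        yr: np.array([m.get(v, 0.0) for v in vendors]) for yr, m in mix.items()
    }
    vend_probs = np.stack([vend_probs_by_year[int(yr)] for yr in year_e])
    vendor_e = _categorical(rng.random(len(t_e)), vend_probs, vendors)

    # cancer onset: first round whose hazard draw fires
    base_inc = np.array([config.incidence(b) for b in AGE_BANDS])
    rr = np.array([config.incidence_density_rr[c] for c in DENSITY_CATEGORIES])
    dens_i = np.vectorize({c: i for i, c in enumerate(DENSITY_CATEGORIES)}.__getitem__)(density_e)
    p_onset = np.clip(base_inc[band_i] * rr[dens_i], 0.0, 1.0)
    hit = rng.random(len(t_e)) < p_onset
    lag = rng.integers(0, config.diagnosis_lag_max_months + 1, size=n)
    u_type = rng.random(n)

    exams = pd.DataFrame(
        {
            "pid": pid_idx,
            "round": round_idx,
            "t": t_e,
            "age_at_exam": age_e,
            "density": density_e,
            "vendor": vendor_e,
            "hit": hit,
        }
    )
    onset = exams[exams["hit"]].groupby("pid", sort=True)["t"].min()
    dx_t = np.full(n, -1, dtype=np.int64)
    dx_t[onset.index.to_numpy()] = onset.to_numpy() + lag[onset.index.to_numpy()]
    diagnosed = dx_t >= 0
    in_situ = diagnosed & (u_type < config.in_situ_fraction)

    # screening stops at diagnosis
    keep = ~diagnosed[pid_idx] | (t_e <= dx_t[pid_idx])
    exams = exams[keep].reset_index(drop=True)
    ne = len(exams)
    pid = exams["pid"].to_numpy()

    months_to_dx = np.where(diagnosed[pid], dx_t[pid] - exams["t"].to_numpy(), -1)
    in_horizon = diagnosed[pid] & (months_to_dx <= score_config.detectability_horizon_months)
    cancer_type = np.where(~diagnosed[pid], "none", np.where(in_situ[pid], "in_situ", "invasive"))

    # latent noise: shared conspicuity factor drives the reader/AI correlation
    reader = score_config.reader
    rho = reader.ai_correlation
    shared = rng.standard_normal(ne)
    p_recall = np.where(
        diagnosed[pid], reader.case_recall(months_to_dx), 1.0 - reader.specificity
    )
    u_reader = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal(ne)
    recall = u_reader > norm.ppf(1.0 - p_recall)

    rounds = exams["round"].to_numpy()
    data = {
        "exam_id": np.array([f"E{p:07d}_{r}" for p, r in zip(pid, rounds)], dtype=object),
        "participant_id": np.array([f"P{p:07d}" for p in pid], dtype=object),
        "exam_year": (exams["t"] // 12).to_numpy(),
        "exam_month": (exams["t"] % 12 + 1).to_numpy(),
        "age_at_exam": exams["age_at_exam"].to_numpy(),
        "density": exams["density"].to_numpy(),
        "vendor": exams["vendor"].to_numpy(),
        "region": region[pid],
        "radiologist_recall": recall,
    }

    band_e2 = age_band(data["age_at_exam"])
    for name in sorted(score_config.systems):
        sys_cfg = score_config.systems[name]
        own = rng.standard_normal(ne)
        noise = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        ctrl_shift = np.zeros(ne)
        case_shift = np.zeros(ne)
        for table, keys in (
            ("vendor_shift", data["vendor"]),
            ("density_shift", data["density"]),
            ("age_shift", band_e2),
        ):
            shifts = getattr(sys_cfg, table)
            if not shifts:
                continue
            for key, (c0, c1) in shifts.items():
                mask = keys == key
                ctrl_shift[mask] += c0
                case_shift[mask] += c1
        for ctype, s in sys_cfg.cancer_type_shift.items():
            case_shift[cancer_type == ctype] += s
        latent = np.where(
            in_horizon,
            sys_cfg.case_mean + case_shift + sys_cfg.case_sd * noise,
            sys_cfg.control_mean + ctrl_shift + sys_cfg.control_sd * noise,
        )
        data[f"score_{name}"] = expit(latent)

    dx_year = np.where(diagnosed[pid], dx_t[pid] // 12, -1)
    dx_month = np.where(diagnosed[pid], dx_t[pid] % 12 + 1, -1)
    data["diagnosis_year"] = pd.array(
        np.where(diagnosed[pid], dx_year, pd.NA), dtype="Int64"
    )
    data["diagnosis_month"] = pd.array(
        np.where(diagnosed[pid], dx_month, pd.NA), dtype="Int64"
    )
    data["cancer_type"] = cancer_type

    out = pd.DataFrame(data)
    cols = list(EXAM_COLUMNS)
    score_cols = [f"score_{s}" for s in sorted(score_config.systems)]
    cols = cols[: cols.index("diagnosis_year")] + score_cols + cols[cols.index("diagnosis_year"):]
    return out[cols]


# ---------------------------------------------------------------------------
# Exam-record validation
# ---------------------------------------------------------------------------


class ExamRecord(BaseModel):
    """One screening examination (exam-level, scores already maximized over
    laterality by the upstream AI systems)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    exam_id: str
    participant_id: str
    exam_year: int
    exam_month: int = Field(ge=1, le=12)
    age_at_exam: int
    density: str
    vendor: str
    region: str
    radiologist_recall: bool
    ai_scores: dict[str, float]
    diagnosis_year: int | None = None
    diagnosis_month: int | None = None
    cancer_type: str = "none"

    @model_validator(mode="after")
    def _invariants(self):
        if not self.ai_scores:
            raise ValueError("ai_scores must be non-empty")
        for k, v in self.ai_scores.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"ai_scores[{k}]={v} outside [0, 1]")
        if self.density not in DENSITY_CATEGORIES:
            raise ValueError(f"density {self.density!r} not in {DENSITY_CATEGORIES}")
        has_dx = self.diagnosis_year is not None
        if has_dx != (self.diagnosis_month is not None):
            raise ValueError("diagnosis_year and diagnosis_month must both be set or absent")
        if has_dx and self.cancer_type == "none":
            raise ValueError("diagnosed exam must carry a cancer_type")
        if not has_dx and self.cancer_type != "none":
            raise ValueError("cancer_type set without a diagnosis date")
        return self


def score_columns(exams: pd.DataFrame) -> list[str]:
    return [c for c in exams.columns if c.startswith("score_")]


def ai_systems(exams: pd.DataFrame) -> list[str]:
    return [c[len("score_"):] for c in score_columns(exams)]


def validate_exam_frame(exams: pd.DataFrame, age_range: tuple[int, int] | None = None) -> None:
    """Check the frame-level invariants of the exam table; raises ValueError
    naming the violated field."""
    scores = score_columns(exams)
    if not scores:
        raise ValueError("ai_scores: no score_<system> columns present")
    for c in scores:
        v = exams[c].to_numpy(dtype=float)
        if np.isnan(v).any() or (v < 0).any() or (v > 1).any():
            raise ValueError(f"{c}: scores outside [0, 1]")
    has_dx = exams["diagnosis_year"].notna()
    if (has_dx != (exams["cancer_type"] != "none")).any():
        raise ValueError("cancer_type: must be 'none' iff diagnosis date absent")
    if age_range is not None:
        a = exams["age_at_exam"]
        if ((a < age_range[0]) | (a > age_range[1])).any():
            raise ValueError("age_at_exam: outside configured age_range")
    per_part = exams.groupby("participant_id")[["diagnosis_year", "diagnosis_month"]].nunique(
        dropna=False
    )
    if (per_part > 1).any().any():
        raise ValueError("diagnosis linkage differs across exams of one participant")


# ---------------------------------------------------------------------------
# Summaries and IO
# ---------------------------------------------------------------------------


def summarize_population(exams: pd.DataFrame, *, window_months: int = 36) -> pd.DataFrame:
    """Stratified participant/exam counts by case-control status.

    Status at exam level follows the reference standard (diagnosis within
    ``window_months`` after the exam); a participant counts as a case in a
    stratum if any of their exams in it is a case exam.  Returns a tidy
    frame (family, level, status, unit, count, pct); percentages sum to 100
    within each (family, status, unit) group.
    """
    if exams.empty:
        raise ValueError("summarize_population: empty exam collection")
    df = exams.copy()
    m2d = month_index(df["diagnosis_year"].astype("float"), df["diagnosis_month"].astype("float")) - month_index(
        df["exam_year"], df["exam_month"]
    )
    df["status"] = np.where(
        df["diagnosis_year"].notna() & (m2d >= 0) & (m2d <= window_months), "case", "control"
    )
    df["age_band"] = age_band(df["age_at_exam"])
    df["menopause"] = np.where(df["age_at_exam"] <= 55, "pre", "post")

    families = {
        "vendor": "vendor",
        "age_band": "age_band",
        "menopause": "menopause",
        "density": "density",
        "cancer_type": "cancer_type",
    }
    rows = []
    for family, col in families.items():
        sub = df
        if family == "cancer_type":
            sub = df[df["status"] == "case"]
            if sub.empty:
                continue
        for status, grp in sub.groupby("status"):
            n_exams = grp.groupby(col, observed=True)["exam_id"].count()
            n_parts = grp.groupby(col, observed=True)["participant_id"].nunique()
            for unit, counts in (("exams", n_exams), ("participants", n_parts)):
                total = counts.sum()
                for level, count in counts.items():
                    rows.append(
                        {
                            "family": family,
                            "level": level,
                            "status": status,
                            "unit": unit,
                            "count": int(count),
                            "pct": 100.0 * count / total if total else 0.0,
                        }
                    )
    overall = df.groupby("status").agg(
        exams=("exam_id", "count"), participants=("participant_id", "nunique")
    )
    for status, row in overall.iterrows():
        for unit in ("exams", "participants"):
            rows.append(
                {
                    "family": "overall",
                    "level": "overall",
                    "status": status,
                    "unit": unit,
                    "count": int(row[unit]),
                    "pct": 100.0,
                }
            )
    return pd.DataFrame(rows)


def write_exams(exams: pd.DataFrame, path: str | Path) -> None:
    """Write the exam table as CSV or Parquet, by file suffix."""
    path = Path(path)
    if path.suffix == ".csv":
        exams.to_csv(path, index=False)
    elif path.suffix in (".parquet", ".pq"):
        exams.to_parquet(path, index=False)
    else:
        raise ValueError(f"unsupported exam-table format {path.suffix!r}")


def read_exams(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        for c in ("diagnosis_year", "diagnosis_month"):
            df[c] = df[c].astype("Int64")
        df["radiologist_recall"] = df["radiologist_recall"].astype(bool)
        return df
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    raise ValueError(f"unsupported exam-table format {path.suffix!r}")
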