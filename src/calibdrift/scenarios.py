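"""Validation-error scenarios as calibration-set / target-set selectors.

Each scenario family captures one way a calibration dataset can fail to
represent the clinical target population:

* ``follow_up``   -- reference standard defined at 12/24/48 months instead
                     of the 36-month baseline;
* ``temporal``    -- cases and controls drawn from different year bands;
* ``age``         -- cases and controls split across the menopause age;
* ``density``     -- restricted mammographic density mixes (A+B, C+D, A+B+C);
* ``cancer_type`` -- only invasive or only in-situ cancers;
* ``vendor``      -- single-vendor calibration for the other vendor's data,
                     or cases and controls from different vendors;
* ``representative`` -- identity selection (the no-error baseline).

Filters are declarative field/operator/value triples in disjunctive normal
form (OR over AND-clauses; the empty filter selects everything), so a
scenario is serializable and its selection is pure and idempotent.

The runner executes the full audit pipeline: label at the (possibly
overridden) window, apply the filters, read off the radiologist CDR on the
representative target, calibrate each AI system on both the target (the
reference) and the filtered calibration set (the mismatch), transfer both
thresholds to the target, and report distortion plus an unpaired DeLong AUC
comparison between the filtered selection and the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .calibrate import (
    DistortionReport,
    calibrate_threshold,
    radiologist_operating_point,
    transfer_and_report,
)
from .metrics import OperatingMetrics, PrevalenceAdjustment
from .refstd import FollowUpWindow, LabeledDataset, label_exams
from .roc import DelongResult, delong_unpaired

__all__ = [
    "Condition",
    "ScenarioSpec",
    "ScenarioResult",
    "UnknownScenarioError",
    "ScenarioInfeasibleError",
    "SCENARIO_FAMILIES",
    "all_scenarios",
    "make_scenario",
    "apply_filter",
    "run_scenario",
]

logger = logging.getLogger("calibdrift.scenarios")

BASELINE_WINDOW_MONTHS = 36
DEFAULT_MENOPAUSE_AGE = 55
DEFAULT_EARLY_YEARS = (2008, 2012)
DEFAULT_LATE_YEARS = (2015, 2019)

_OPS = {
    "eq": lambda col, v: col == v,
    "ne": lambda col, v: col != v,
    "le": lambda col, v: col <= v,
    "lt": lambda col, v: col < v,
    "ge": lambda col, v: col >= v,
    "gt": lambda col, v: col > v,
    "in": lambda col, v: col.isin(list(v)),
}


class Condition(NamedTuple):
    """One field/operator/value predicate over an exam row plus its label."""

    field: str
    op: str
    value: object


#: OR over AND-clauses; () selects everything.
Filter = tuple[tuple[Condition, ...], ...]

IDENTITY: Filter = ()


class UnknownScenarioError(ValueError):
    def __init__(self, family: str, variant: str | None, valid):
        super().__init__(
            f"unknown scenario {family!r}/{variant!r}; valid: "
            + ", ".join(f"{f}/{v}" for f, v in valid)
        )


class ScenarioInfeasibleError(RuntimeError):
    """A filter emptied one class of the calibration or target set."""


@dataclass(frozen=True)
class ScenarioSpec:
    family: str
    variant: str
    calibration_filter: Filter = IDENTITY
    target_filter: Filter = IDENTITY
    window_override: FollowUpWindow | None = None
    description: str = ""

    @property
    def name(self) -> str:
        return f"{self.family}/{self.variant}"


def apply_filter(dataset: LabeledDataset, filt: Filter) -> LabeledDataset:
    """Select the exams matching any clause (pure; applying twice = once)."""
    if not filt:
        return dataset
    df = dataset.exams
    labels = pd.Series(dataset.labels.to_numpy(), index=df.index)
    mask = np.zeros(len(df), dtype=bool)
    for clause in filt:
        m = np.ones(len(df), dtype=bool)
        for cond in clause:
            if cond.op not in _OPS:
                raise ValueError(f"unknown filter operator {cond.op!r}")
            col = labels if cond.field == "label" else df[cond.field]
            m &= np.asarray(_OPS[cond.op](col, cond.value))
        mask |= m
    return dataset.subset(mask)


def _label_band(label: str, years: tuple[int, int]) -> tuple[Condition, ...]:
    return (
        Condition("label", "eq", label),
        Condition("exam_year", "ge", years[0]),
        Condition("exam_year", "le", years[1]),
    )


def _registry(
    *,
    menopause_age: int,
    early_years: tuple[int, int],
    late_years: tuple[int, int],
    vendors: tuple[str, str] = ("GE", "Philips"),
) -> dict[tuple[str, str], ScenarioSpec]:
    ge, ph = vendors
    case = Condition("label", "eq", "case")
    control = Condition("label", "eq", "control")

    def spec(family, variant, cal=IDENTITY, target=IDENTITY, window=None, desc=""):
        return ScenarioSpec(
            family, variant, cal, target,
            FollowUpWindow(window) if window else None, desc,
        )

    entries = [
        spec("representative", "overall", desc="identity selection, no validation error"),
        # 1. reference standard at mismatched follow-up windows
        spec("follow_up", "12m", window=12, desc="1-year follow-up reference standard"),
        spec("follow_up", "24m", window=24, desc="2-year follow-up reference standard"),
        spec("follow_up", "48m", window=48, desc="4-year follow-up reference standard"),
        # 2. temporal selection
        spec(
            "temporal", "early_cases_late_controls",
            cal=(_label_band("case", early_years), _label_band("control", late_years)),
            desc=f"cases {early_years[0]}-{early_years[1]}, controls {late_years[0]}-{late_years[1]}",
        ),
        spec(
            "temporal", "early_controls_late_cases",
            cal=(_label_band("control", early_years), _label_band("case", late_years)),
            desc=f"controls {early_years[0]}-{early_years[1]}, cases {late_years[0]}-{late_years[1]}",
        ),
        # 3. age / menopause mixes
        spec(
            "age", "post_case_pre_control",
            cal=(
                (case, Condition("age_at_exam", "gt", menopause_age)),
                (control, Condition("age_at_exam", "le", menopause_age)),
            ),
            desc=f"post-menopause cases (>{menopause_age}) and pre-menopause controls",
        ),
        spec(
            "age", "pre_case_post_control",
            cal=(
                (case, Condition("age_at_exam", "le", menopause_age)),
                (control, Condition("age_at_exam", "gt", menopause_age)),
            ),
            desc=f"pre-menopause cases (<={menopause_age}) and post-menopause controls",
        ),
        # 4. mammographic density mixes
        spec(
            "density", "AB_only",
            cal=((Condition("density", "in", ("A", "B")),),),
            desc="density A and B only",
        ),
        spec(
            "density", "CD_only",
            cal=((Condition("density", "in", ("C", "D")),),),
            desc="density C and D only",
        ),
        spec(
            "density", "ABC_only",
            cal=((Condition("density", "in", ("A", "B", "C")),),),
            desc="density A, B and C only (category D removed)",
        ),
        # 5. cancer characteristics
        spec(
            "cancer_type", "invasive_only",
            cal=((control,), (case, Condition("cancer_type", "eq", "invasive"))),
            desc="invasive cancers only",
        ),
        spec(
            "cancer_type", "in_situ_only",
            cal=((control,), (case, Condition("cancer_type", "eq", "in_situ"))),
            desc="in-situ cancers only",
        ),
        # 6. imaging equipment manufacturer
        spec(
            "vendor", "philips_calibration_ge_target",
            cal=((Condition("vendor", "eq", ph),),),
            target=((Condition("vendor", "eq", ge),),),
            desc=f"calibrated on {ph}, applied to {ge} data",
        ),
        spec(
            "vendor", "ge_calibration_philips_target",
            cal=((Condition("vendor", "eq", ge),),),
            target=((Condition("vendor", "eq", ph),),),
            desc=f"calibrated on {ge}, applied to {ph} data",
        ),
        spec(
            "vendor", "ge_case_philips_control",
            cal=(
                (case, Condition("vendor", "eq", ge)),
                (control, Condition("vendor", "eq", ph)),
            ),
            desc=f"{ge} cases mixed with {ph} controls",
        ),
        spec(
            "vendor", "philips_case_ge_control",
            cal=(
                (case, Condition("vendor", "eq", ph)),
                (control, Condition("vendor", "eq", ge)),
            ),
            desc=f"{ph} cases mixed with {ge} controls",
        ),
    ]
    return {(s.family, s.variant): s for s in entries}


SCENARIO_FAMILIES = (
    "representative", "follow_up", "temporal", "age", "density", "cancer_type", "vendor",
)


def all_scenarios(**kwargs) -> list[ScenarioSpec]:
    """Every published scenario variant (one per table row of the validation
    error catalogue)."""
    return list(_registry(
        menopause_age=kwargs.pop("menopause_age", DEFAULT_MENOPAUSE_AGE),
        early_years=kwargs.pop("early_years", DEFAULT_EARLY_YEARS),
        late_years=kwargs.pop("late_years", DEFAULT_LATE_YEARS),
        **kwargs,
    ).values())


def make_scenario(
    family: str,
    variant: str | None = None,
    *,
    menopause_age: int = DEFAULT_MENOPAUSE_AGE,
    early_years: tuple[int, int] = DEFAULT_EARLY_YEARS,
    late_years: tuple[int, int] = DEFAULT_LATE_YEARS,
) -> ScenarioSpec:
    """Look up a scenario by family and variant.

    The menopause split age and the temporal year bands are exposed because
    they are program-specific conventions, not universal constants.
    """
    reg = _registry(
        menopause_age=menopause_age, early_years=early_years, late_years=late_years
    )
    if variant is None:
        matches = [k for k in reg if k[0] == family]
        if len(matches) == 1:
            return reg[matches[0]]
        raise UnknownScenarioError(family, variant, sorted(reg))
    key = (family, variant)
    if key not in reg:
        raise UnknownScenarioError(family, variant, sorted(reg))
    return reg[key]


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    radiologist: OperatingMetrics
    reports: dict[str, DistortionReport]
    auc_tests: dict[str, DelongResult]
    counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-system table mirroring a published summary table:
        scenario, system, AUC comparison and percent changes with CIs."""
        rows = []
        for system, rep in self.reports.items():
            test = self.auc_tests[system]
            rows.append(
                {
                    "scenario": self.spec.name,
                    "ai_system": system,
                    "auc_selection": test.auc_a,
                    "auc_representative": test.auc_b,
                    "delong_p": test.p,
                    "pct_change_cdr": rep.pct_change_cdr,
                    "pct_change_cdr_ci_low": (rep.ci_pct_change_cdr or (np.nan, np.nan))[0],
                    "pct_change_cdr_ci_high": (rep.ci_pct_change_cdr or (np.nan, np.nan))[1],
                    "pct_change_fpr": rep.pct_change_fpr,
                    "pct_change_fpr_ci_low": (rep.ci_pct_change_fpr or (np.nan, np.nan))[0],
                    "pct_change_fpr_ci_high": (rep.ci_pct_change_fpr or (np.nan, np.nan))[1],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scenario": self.spec.name,
            "description": self.spec.description,
            "counts": self.counts,
            "radiologist": self.radiologist.to_dict(),
            "reports": {k: v.to_dict() for k, v in self.reports.items()},
            "auc_tests": {k: v.to_dict() for k, v in self.auc_tests.items()},
        }


def _require_two_classes(ds: LabeledDataset, what: str, spec: ScenarioSpec) -> None:
    if ds.n_cases == 0 or ds.n_controls == 0:
        raise ScenarioInfeasibleError(
            f"scenario {spec.name}: {what} set has {ds.n_cases} cases / "
            f"{ds.n_controls} controls"
        )


def run_scenario(
    spec: ScenarioSpec,
    exams: pd.DataFrame,
    ai_systems: Sequence[str] | None = None,
    *,
    baseline_window: int = BASELINE_WINDOW_MONTHS,
    collection_end: tuple[int, int] | None = None,
    adjustment: PrevalenceAdjustment | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ScenarioResult:
    """Execute one scenario end to end against the representative baseline.

    The target population is always labelled at ``baseline_window``; a
    follow-up scenario re-labels only the calibration set at its overridden
    window, so the distortion is always evaluated against the 36-month
    representative reference standard.
    """
    target_all = label_exams(exams, baseline_window, collection_end=collection_end)
    if spec.window_override is not None:
        cal_all = label_exams(exams, spec.window_override, collection_end=collection_end)
    else:
        cal_all = target_all

    target = apply_filter(target_all, spec.target_filter)
    calibration = apply_filter(cal_all, spec.calibration_filter)
    _require_two_classes(target, "target", spec)
    _require_two_classes(calibration, "calibration", spec)

    counts = {
        "calibration_cases": calibration.n_cases,
        "calibration_controls": calibration.n_controls,
        "target_cases": target.n_cases,
        "target_controls": target.n_controls,
    }
    logger.info(
        "scenario %s: calibration %d cases / %d controls; target %d cases / %d controls",
        spec.name, *counts.values(),
    )

    systems = list(ai_systems) if ai_systems is not None else target.ai_systems
    rad = radiologist_operating_point(target, adjustment, with_ci=False)
    target_cdr = rad.cdr_per_1000

    reports: dict[str, DistortionReport] = {}
    auc_tests: dict[str, DelongResult] = {}
    for system in systems:
        ref_cal = calibrate_threshold(target, system, target_cdr)
        mis_cal = calibrate_threshold(calibration, system, target_cdr)
        reports[system] = transfer_and_report(
            mis_cal,
            target,
            ref_cal,
            adjustment=adjustment,
            n_bootstrap=n_bootstrap,
            seed=seed,
            scenario=spec.name,
        )
        auc_tests[system] = delong_unpaired(
            calibration.scores(system),
            calibration.case_mask,
            target.scores(system),
            target.case_mask,
        )
    return ScenarioResult(spec, rad, reports, auc_tests, counts)
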