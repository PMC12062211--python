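"""Screening accuracy metrics and prevalence correction.

Point metrics derive from the exam-level confusion matrix: sensitivity,
specificity, FPR, FNR, PPV, plus the program rates AIR (abnormal
interpretation rate) and CDR (cancer detection rate), both per 1000 exams.

A case-enriched case-control dataset misstates every prevalence-dependent
metric (PPV, CDR, AIR).  Two corrections to cohort prevalence are provided:

* *upscaling*: every control exam is duplicated the same whole number of
  times so the case:control ratio matches the cohort's;
* *weighted bootstrap*: participants are resampled with class weights chosen
  so the expected case fraction equals the cohort's; metrics are averaged
  over replicates and the 2.5/97.5 percentiles give the interval.

Confidence intervals everywhere are participant-level stratified bootstrap
percentile intervals (resampling participants, not exams, so repeated exams
of one woman travel together).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .refstd import LabeledDataset

__all__ = [
    "OperatingMetrics",
    "PrevalenceAdjustment",
    "MissingDecisionsError",
    "UpscaleError",
    "compute_metrics",
    "upscale_controls",
    "weighted_bootstrap_metrics",
    "metrics_to_frame",
]

DEFAULT_BOOTSTRAP = 1000
_CI_METRICS = ("sensitivity", "specificity", "fpr", "fnr", "ppv", "air_per_1000", "cdr_per_1000")


class MissingDecisionsError(KeyError):
    def __init__(self, exam_ids):
        self.exam_ids = list(exam_ids)
        shown = self.exam_ids[:10]
        super().__init__(f"decisions missing for {len(self.exam_ids)} exam(s), e.g. {shown}")


class UpscaleError(ValueError):
    """Raised when the dataset is less case-enriched than the cohort, so the
    whole-copy replication factor would be < 1; use the weighted bootstrap."""


class PrevalenceAdjustment(BaseModel):
    """How (whether) to correct metrics to cohort prevalence.

    ``cohort_case_count`` / ``cohort_control_count`` are exam counts from the
    cohort dataset and define the target ratio.  Ignored when method='none'.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    method: Literal["none", "upscale", "weighted_bootstrap"] = "none"
    cohort_case_count: int = Field(default=1, gt=0)
    cohort_control_count: int = Field(default=1, gt=0)
    n_bootstrap: int = Field(default=DEFAULT_BOOTSTRAP, gt=0)
    seed: int = 0

    @property
    def target_controls_per_case(self) -> float:
        return self.cohort_control_count / self.cohort_case_count

    @property
    def cohort_case_fraction(self) -> float:
        return self.cohort_case_count / (self.cohort_case_count + self.cohort_control_count)

    @classmethod
    def none(cls, n_bootstrap: int = DEFAULT_BOOTSTRAP, seed: int = 0) -> "PrevalenceAdjustment":
        return cls(method="none", n_bootstrap=n_bootstrap, seed=seed)


@dataclass
class OperatingMetrics:
    """Confusion matrix and derived screening metrics at one operating point.

    Counts are floats to accommodate weighted paths.  Metrics that are
    undefined for the given counts (e.g. PPV with no positive calls) are
    ``None`` and named in ``flags`` rather than silently NaN.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    sensitivity: float | None
    specificity: float | None
    fpr: float | None
    fnr: float | None
    ppv: float | None
    air_per_1000: float
    cdr_per_1000: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    adjustment_method: str = "none"

    @property
    def n_exams(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_counts(
        cls, tp: float, fp: float, tn: float, fn: float, adjustment_method: str = "none"
    ) -> "OperatingMetrics":
        flags = []
        pos, neg, called = tp + fn, fp + tn, tp + fp
        total = pos + neg

        def ratio(num, den, name):
            if den == 0:
                flags.append(f"{name}_undefined")
                return None
            return num / den

        sens = ratio(tp, pos, "sensitivity")
        spec = ratio(tn, neg, "specificity")
        return cls(
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            sensitivity=sens,
            specificity=spec,
            fpr=None if spec is None else 1.0 - spec,
            fnr=None if sens is None else 1.0 - sens,
            ppv=ratio(tp, called, "ppv"),
            air_per_1000=1000.0 * called / total,
            cdr_per_1000=1000.0 * tp / total,
            flags=flags,
            adjustment_method=adjustment_method,
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "ppv": self.ppv,
            "air_per_1000": self.air_per_1000,
            "cdr_per_1000": self.cdr_per_1000,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "flags": self.flags,
            "adjustment_method": self.adjustment_method,
        }


def metrics_to_frame(metrics: OperatingMetrics, n_effective: float | None = None) -> pd.DataFrame:
    """One row per metric: name, estimate, ci_low, ci_high, n_effective,
    adjustment_method (the CSV export shape)."""
    rows = []
    for name in _CI_METRICS:
        est = getattr(metrics, name)
        lo, hi = metrics.ci.get(name, (np.nan, np.nan))
        rows.append(
            {
                "metric": name,
                "estimate": np.nan if est is None else est,
                "ci_low": lo,
                "ci_high": hi,
                "n_effective": metrics.n_exams if n_effective is None else n_effective,
                "adjustment_method": metrics.adjustment_method,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decision alignment and per-participant aggregation
# ---------------------------------------------------------------------------


def _align_decisions(dataset: LabeledDataset, decisions) -> np.ndarray:
    ids = dataset.exams["exam_id"]
    if isinstance(decisions, pd.Series):
        aligned = decisions.reindex(ids)
        if aligned.isna().any():
            raise MissingDecisionsError(ids[aligned.isna().to_numpy()])
        return aligned.to_numpy(dtype=bool)
    if isinstance(decisions, Mapping):
        missing = [e for e in ids if e not in decisions]
        if missing:
            raise MissingDecisionsError(missing)
        return np.fromiter((bool(decisions[e]) for e in ids), dtype=bool, count=len(ids))
    arr = np.asarray(decisions, dtype=bool)
    if len(arr) != len(ids):
        raise MissingDecisionsError(ids[len(arr):] if len(arr) < len(ids) else [])
    return arr


def _confusion(y: np.ndarray, d: np.ndarray, w: np.ndarray | None = None):
    if w is None:
        w = np.ones(len(y))
    tp = float(w[y & d].sum())
    fp = float(w[~y & d].sum())
    tn = float(w[~y & ~d].sum())
    fn = float(w[y & ~d].sum())
    return tp, fp, tn, fn


def _participant_cells(dataset: LabeledDataset, d: np.ndarray, control_weight: float = 1.0):
    """Aggregate confusion cells per participant.

    Returns (case_matrix, control_matrix), each P x 4 with columns
    (tp, fp, tn, fn); a participant is on the case side if any exam is a
    case.  Control exams get ``control_weight`` (the upscale factor).
    """
    y = dataset.case_mask
    w = np.where(y, 1.0, control_weight)
    cells = pd.DataFrame(
        {
            "pid": dataset.participants.to_numpy(),
            "tp": w * (y & d),
            "fp": w * (~y & d),
            "tn": w * (~y & ~d),
            "fn": w * (y & ~d),
            "is_case": y,
        }
    )
    agg = cells.groupby("pid", sort=True).agg(
        tp=("tp", "sum"), fp=("fp", "sum"), tn=("tn", "sum"), fn=("fn", "sum"),
        is_case=("is_case", "any"),
    )
    case_m = agg[agg["is_case"]][["tp", "fp", "tn", "fn"]].to_numpy(dtype=float)
    ctrl_m = agg[~agg["is_case"]][["tp", "fp", "tn", "fn"]].to_numpy(dtype=float)
    return case_m, ctrl_m


def _bootstrap_sums(matrix: np.ndarray, rng: np.random.Generator, b: int, chunk: int = 200):
    """B stratum resample sums: each replicate draws len(matrix) participants
    with replacement (multinomial weights) and sums their cells."""
    p = len(matrix)
    if p == 0:
        return np.zeros((b, matrix.shape[1]))
    probs = np.full(p, 1.0 / p)
    out = np.empty((b, matrix.shape[1]))
    for lo in range(0, b, chunk):
        hi = min(lo + chunk, b)
        counts = rng.multinomial(p, probs, size=hi - lo)
        out[lo:hi] = counts @ matrix
    return out


def _metric_array(tp, fp, tn, fn):
    """Vectorized metric computation over bootstrap replicates; undefined
    cells become NaN (handled by nan-percentiles)."""
    pos, neg, called, total = tp + fn, fp + tn, tp + fp, tp + fp + tn + fn
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(pos > 0, tp / np.where(pos > 0, pos, 1), np.nan)
        spec = np.where(neg > 0, tn / np.where(neg > 0, neg, 1), np.nan)
        ppv = np.where(called > 0, tp / np.where(called > 0, called, 1), np.nan)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "fpr": 1.0 - spec,
        "fnr": 1.0 - sens,
        "ppv": ppv,
        "air_per_1000": 1000.0 * called / total,
        "cdr_per_1000": 1000.0 * tp / total,
    }


def _percentile_ci(samples: dict[str, np.ndarray]) -> dict[str, tuple[float, float]]:
    ci = {}
    for name, arr in samples.items():
        if np.isnan(arr).all():
            continue
        lo, hi = np.nanpercentile(arr, [2.5, 97.5])
        ci[name] = (float(lo), float(hi))
    return ci


def _bootstrap_ci(
    dataset: LabeledDataset, d: np.ndarray, *, control_weight: float, b: int, seed: int
) -> dict[str, tuple[float, float]]:
    rng = np.random.default_rng(seed)
    case_m, ctrl_m = _participant_cells(dataset, d, control_weight)
    sums = _bootstrap_sums(case_m, rng, b) + _bootstrap_sums(ctrl_m, rng, b)
    return _percentile_ci(_metric_array(*sums.T))


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def _replication_factor(dataset: LabeledDataset, target_controls_per_case: float) -> int:
    n_cases, n_controls = dataset.n_cases, dataset.n_controls
    if n_controls == 0:
        raise UpscaleError("dataset has no controls to upscale")
    if n_cases == 0:
        raise UpscaleError("dataset has no cases; the cohort ratio is undefined")
    observed = n_controls / n_cases
    r = round(target_controls_per_case / observed)
    if r < 1:
        raise UpscaleError(
            f"replication factor {r} < 1 (dataset already less case-enriched than the "
            f"cohort); use method='weighted_bootstrap'"
        )
    return int(r)


def upscale_controls(
    dataset: LabeledDataset, target_controls_per_case: float
) -> LabeledDataset:
    """Physically replicate each control exam ``r`` times, where ``r`` is the
    nearest whole number matching the cohort control:case ratio.  Replicates
    carry a ``replicate`` index and suffixed exam ids; case exams untouched."""
    r = _replication_factor(dataset, target_controls_per_case)
    df = dataset.to_frame()
    df["replicate"] = 0
    if r > 1:
        ctrl = df[df["label"] == "control"]
        copies = []
        for i in range(1, r):
            c = ctrl.copy()
            c["replicate"] = i
            c["exam_id"] = c["exam_id"] + f"#rep{i}"
            copies.append(c)
        df = pd.concat([df] + copies, ignore_index=True)
    labels = pd.Series(df["label"].to_numpy(), index=df["exam_id"], name="label")
    exams = df.drop(columns=["label"])
    prov = f"{dataset.provenance} | upscale(r={r})"
    return LabeledDataset(exams, labels, dataset.window, prov)


def weighted_bootstrap_metrics(
    dataset: LabeledDataset, decisions, adjustment: PrevalenceAdjustment
) -> OperatingMetrics:
    """Prevalence-corrected metrics by participant-level weighted resampling.

    Each of B replicates draws ``P`` participants with replacement with class
    weights set so the expected case fraction equals the cohort's; metrics
    are computed unweighted per replicate.  Point estimate = replicate mean,
    CI = 2.5/97.5 percentiles.  Replicates without any case exam are dropped
    and counted; more than 10% dropped raises a flag.
    """
    if adjustment.n_bootstrap < 100:
        raise ValueError("weighted bootstrap needs n_bootstrap >= 100")
    d = _align_decisions(dataset, decisions)
    rng = np.random.default_rng(adjustment.seed)
    case_m, ctrl_m = _participant_cells(dataset, d)
    n_case_p, n_ctrl_p = len(case_m), len(ctrl_m)
    if n_case_p == 0 or n_ctrl_p == 0:
        raise ValueError("weighted bootstrap needs both case and control participants")
    p_case = adjustment.cohort_case_fraction
    matrix = np.vstack([case_m, ctrl_m])
    probs = np.concatenate(
        [
            np.full(n_case_p, p_case / n_case_p),
            np.full(n_ctrl_p, (1.0 - p_case) / n_ctrl_p),
        ]
    )
    total_p = n_case_p + n_ctrl_p
    b = adjustment.n_bootstrap
    sums = np.empty((b, 4))
    chunk = max(1, int(2e6 // total_p))
    for lo in range(0, b, chunk):
        hi = min(lo + chunk, b)
        counts = rng.multinomial(total_p, probs, size=hi - lo)
        sums[lo:hi] = counts @ matrix

    pos = sums[:, 0] + sums[:, 3]
    ok = pos > 0
    dropped = int((~ok).sum())
    samples = _metric_array(*sums[ok].T)
    point = {k: float(np.nanmean(v)) for k, v in samples.items()}
    counts_mean = sums[ok].mean(axis=0)
    m = OperatingMetrics(
        tp=counts_mean[0],
        fp=counts_mean[1],
        tn=counts_mean[2],
        fn=counts_mean[3],
        sensitivity=point["sensitivity"],
        specificity=point["specificity"],
        fpr=point["fpr"],
        fnr=point["fnr"],
        ppv=point["ppv"] if not np.isnan(point["ppv"]) else None,
        air_per_1000=point["air_per_1000"],
        cdr_per_1000=point["cdr_per_1000"],
        ci=_percentile_ci(samples),
        adjustment_method="weighted_bootstrap",
    )
    if dropped:
        m.flags.append(f"degenerate_replicates_dropped={dropped}")
    if dropped > 0.1 * b:
        m.flags.append("warning_over_10pct_replicates_dropped")
    return m


def compute_metrics(
    dataset: LabeledDataset,
    decisions,
    adjustment: PrevalenceAdjustment | None = None,
    *,
    with_ci: bool = True,
) -> OperatingMetrics:
    """Operating metrics for binary decisions over a labelled dataset.

    ``decisions`` may be a Series/dict keyed by exam_id or an aligned bool
    array; every exam must be covered.  The adjustment selects the counting
    path; see the module docstring.
    """
    adjustment = adjustment or PrevalenceAdjustment.none()
    d = _align_decisions(dataset, decisions)
    y = dataset.case_mask

    if adjustment.method == "weighted_bootstrap":
        return weighted_bootstrap_metrics(dataset, d, adjustment)

    control_weight = 1.0
    if adjustment.method == "upscale":
        control_weight = float(
            _replication_factor(dataset, adjustment.target_controls_per_case)
        )
    w = np.where(y, 1.0, control_weight)
    m = OperatingMetrics.from_counts(
        *_confusion(y, d, w), adjustment_method=adjustment.method
    )
    if with_ci:
        m.ci = _bootstrap_ci(
            dataset,
            d,
            control_weight=control_weight,
            b=adjustment.n_bootstrap,
            seed=adjustment.seed,
        )
    return m
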