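"""Operating-point calibration and calibration-transfer distortion.

"Calibration" here is operating-point selection, not probability
calibration: the AI decision threshold is chosen so the AI cancer detection
rate (CDR per 1000 exams) on a calibration dataset is as close as possible
to a target rate -- in the intended workflow, the radiologist double-reading
CDR on the representative population.  An exam is called positive when its
score is *strictly greater* than the threshold, so a +inf sentinel expresses
"call nothing" and a -inf sentinel "call everything".

Transferring a threshold calibrated on a non-representative dataset to the
representative target population distorts CDR and FPR; the distortion report
quantifies the signed percent change against a reference threshold
calibrated on the target itself, with joint participant-bootstrap CIs (both
operating points evaluated on the same resamples, thresholds held fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    OperatingMetrics,
    PrevalenceAdjustment,
    _bootstrap_sums,
    compute_metrics,
)
from .refstd import LabeledDataset

__all__ = [
    "ThresholdCalibration",
    "DistortionReport",
    "radiologist_operating_point",
    "calibrate_threshold",
    "transfer_and_report",
]


@dataclass
class ThresholdCalibration:
    ai_system_id: str
    threshold: float
    target_cdr_per_1000: float
    achieved_cdr_per_1000: float
    saturated: bool = False
    calibration_provenance: str = ""

    def decisions(self, dataset: LabeledDataset) -> np.ndarray:
        return dataset.scores(self.ai_system_id) > self.threshold

    def to_dict(self) -> dict:
        return {
            "ai_system_id": self.ai_system_id,
            "threshold": self.threshold,
            "target_cdr_per_1000": self.target_cdr_per_1000,
            "achieved_cdr_per_1000": self.achieved_cdr_per_1000,
            "saturated": self.saturated,
            "calibration_provenance": self.calibration_provenance,
        }


@dataclass
class DistortionReport:
    """Signed percent change in CDR and FPR caused by a mismatched
    calibration, negative = reduction.  ``None`` with a flag when the
    reference rate is zero (percent change undefined)."""

    ai_system_id: str
    pct_change_cdr: float | None
    pct_change_fpr: float | None
    ci_pct_change_cdr: tuple[float, float] | None
    ci_pct_change_fpr: tuple[float, float] | None
    reference_metrics: OperatingMetrics
    mismatched_metrics: OperatingMetrics
    reference_threshold: float
    mismatched_threshold: float
    scenario: str = ""
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ai_system_id": self.ai_system_id,
            "pct_change_cdr": self.pct_change_cdr,
            "pct_change_fpr": self.pct_change_fpr,
            "ci_pct_change_cdr": self.ci_pct_change_cdr,
            "ci_pct_change_fpr": self.ci_pct_change_fpr,
            "reference_threshold": self.reference_threshold,
            "mismatched_threshold": self.mismatched_threshold,
            "scenario": self.scenario,
            "flags": self.flags,
            "reference_metrics": self.reference_metrics.to_dict(),
            "mismatched_metrics": self.mismatched_metrics.to_dict(),
        }


def radiologist_operating_point(
    dataset: LabeledDataset, adjustment: PrevalenceAdjustment | None = None, *,
    with_ci: bool = True,
) -> OperatingMetrics:
    """Metrics of the consensus double-reading recall decision."""
    decisions = dataset.exams["radiologist_recall"].to_numpy(dtype=bool)
    return compute_metrics(dataset, decisions, adjustment, with_ci=with_ci)


def calibrate_threshold(
    dataset: LabeledDataset, ai_system_id: str, target_cdr_per_1000: float
) -> ThresholdCalibration:
    """Threshold whose CDR on the calibration set is nearest the target.

    Candidates are the observed scores plus +/- infinity sentinels; the
    positivity rule is score > threshold.  Ties in |CDR - target| break
    toward the higher CDR (higher sensitivity).  When the target exceeds the
    maximum achievable CDR (every exam called positive), the -inf sentinel is
    returned with a saturation flag.
    """
    if target_cdr_per_1000 < 0:
        raise ValueError("target CDR must be >= 0")
    s = dataset.scores(ai_system_id)
    y = dataset.case_mask
    n = len(s)
    if n == 0 or y.all() or not y.any():
        raise ValueError("calibration dataset must contain both classes")

    # Unique descending candidate thresholds; the positivity rule is strict
    # (score > t), so the case count at candidate v_i is the cumulative case
    # count through the *previous* unique value's block.
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    uniq_last = np.r_[s_sorted[1:] != s_sorted[:-1], True]  # last index of each unique value
    cum_cases = np.cumsum(y_sorted)[uniq_last]
    values = s_sorted[uniq_last]
    candidates = np.r_[np.inf, values, -np.inf]
    cases_above = np.r_[0, 0, cum_cases[:-1], y.sum()]

    cdr = 1000.0 * cases_above / n
    max_cdr = cdr[-1]
    err = np.abs(cdr - target_cdr_per_1000)
    best = np.nonzero(err == err.min())[0]
    # ties in |CDR - target| break toward the higher CDR (cdr is
    # non-decreasing along candidates, so that is the last best index);
    # among candidates achieving that same CDR, keep the highest threshold
    # (fewest positive calls)
    best_cdr = cdr[best[-1]]
    idx = best[cdr[best] == best_cdr][0]
    if target_cdr_per_1000 >= max_cdr:
        # saturation: even calling everything cannot exceed the target, so
        # return the minimum threshold (call-everything sentinel)
        idx = len(candidates) - 1
    return ThresholdCalibration(
        ai_system_id=ai_system_id,
        threshold=float(candidates[idx]),
        target_cdr_per_1000=float(target_cdr_per_1000),
        achieved_cdr_per_1000=float(cdr[idx]),
        saturated=bool(target_cdr_per_1000 > max_cdr),
        calibration_provenance=dataset.provenance,
    )


def _pct_change(mismatch: float | None, reference: float | None):
    if not reference:
        return None
    return 100.0 * (mismatch - reference) / reference


def transfer_and_report(
    calibration: ThresholdCalibration,
    target_dataset: LabeledDataset,
    reference_calibration: ThresholdCalibration,
    *,
    adjustment: PrevalenceAdjustment | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    scenario: str = "",
) -> DistortionReport:
    """Apply mismatched and reference thresholds to the target population and
    report signed percent changes in CDR and FPR with joint bootstrap CIs."""
    if calibration.ai_system_id != reference_calibration.ai_system_id:
        raise ValueError("calibrations compare different AI systems")
    d_mis = calibration.decisions(target_dataset)
    d_ref = reference_calibration.decisions(target_dataset)
    m_mis = compute_metrics(target_dataset, d_mis, adjustment, with_ci=False)
    m_ref = compute_metrics(target_dataset, d_ref, adjustment, with_ci=False)

    flags = []
    pct_cdr = _pct_change(m_mis.cdr_per_1000, m_ref.cdr_per_1000)
    pct_fpr = _pct_change(m_mis.fpr, m_ref.fpr)
    if pct_cdr is None:
        flags.append("pct_change_cdr_undefined")
    if pct_fpr is None:
        flags.append("pct_change_fpr_undefined")

    ci_cdr = ci_fpr = None
    if n_bootstrap > 0 and pct_cdr is not None and pct_fpr is not None:
        ci_cdr, ci_fpr = _joint_pct_change_ci(
            target_dataset, d_mis, d_ref, n_bootstrap=n_bootstrap, seed=seed
        )
    return DistortionReport(
        ai_system_id=calibration.ai_system_id,
        pct_change_cdr=pct_cdr,
        pct_change_fpr=pct_fpr,
        ci_pct_change_cdr=ci_cdr,
        ci_pct_change_fpr=ci_fpr,
        reference_metrics=m_ref,
        mismatched_metrics=m_mis,
        reference_threshold=reference_calibration.threshold,
        mismatched_threshold=calibration.threshold,
        scenario=scenario,
        flags=flags,
    )


def _joint_pct_change_ci(dataset, d_mis, d_ref, *, n_bootstrap, seed):
    """Percentile CI of the percent changes over stratified participant
    resamples of the target, evaluating both thresholds on each replicate."""
    y = dataset.case_mask
    cells = pd.DataFrame(
        {
            "pid": dataset.participants.to_numpy(),
            "n": 1.0,
            "tp_mis": (y & d_mis).astype(float),
            "fp_mis": (~y & d_mis).astype(float),
            "neg": (~y).astype(float),
            "tp_ref": (y & d_ref).astype(float),
            "fp_ref": (~y & d_ref).astype(float),
            "is_case": y,
        }
    )
    agg = cells.groupby("pid", sort=True).agg(
        n=("n", "sum"), tp_mis=("tp_mis", "sum"), fp_mis=("fp_mis", "sum"),
        neg=("neg", "sum"), tp_ref=("tp_ref", "sum"), fp_ref=("fp_ref", "sum"),
        is_case=("is_case", "any"),
    )
    cols = ["n", "tp_mis", "fp_mis", "neg", "tp_ref", "fp_ref"]
    case_m = agg[agg["is_case"]][cols].to_numpy(dtype=float)
    ctrl_m = agg[~agg["is_case"]][cols].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    sums = _bootstrap_sums(case_m, rng, n_bootstrap) + _bootstrap_sums(ctrl_m, rng, n_bootstrap)
    n, tp_mis, fp_mis, neg, tp_ref, fp_ref = sums.T
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_cdr = 100.0 * (tp_mis - tp_ref) / np.where(tp_ref > 0, tp_ref, np.nan)
        fpr_mis = fp_mis / np.where(neg > 0, neg, np.nan)
        fpr_ref = fp_ref / np.where(neg > 0, neg, np.nan)
        pct_fpr = 100.0 * (fpr_mis - fpr_ref) / np.where(fpr_ref > 0, fpr_ref, np.nan)

    def ci(arr):
        if np.isnan(arr).all():
            return None
        lo, hi = np.nanpercentile(arr, [2.5, 97.5])
        return (float(lo), float(hi))

    return ci(pct_cdr), ci(pct_fpr)
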