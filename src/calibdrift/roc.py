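"""ROC curves, AUC, and DeLong comparisons.

The AUC point estimate is the trapezoid integral of the empirical ROC, which
equals the normalized Mann-Whitney U statistic with ties counted one half.
Variances and AUC-difference tests use DeLong's structural components
(placement values): for case scores X_i and control scores Y_j,

    V10_i = mean_j psi(X_i, Y_j),   V01_j = mean_i psi(X_i, Y_j),
    psi = 1 if X > Y, 1/2 if tied, else 0,

and var(AUC) = var(V10)/m + var(V01)/n.  The paired test includes the
covariance of the two systems' components; the unpaired variant compares
AUCs from two independent datasets by summing their variances.  Comparing
overlapping subsets with the unpaired test violates independence and makes
the test conservative; a warning is emitted when overlap is detectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocResult",
    "DelongResult",
    "SingleClassError",
    "roc_curve",
    "delong_paired",
    "delong_unpaired",
]


class SingleClassError(ValueError):
    """Scores contain only one class; no ROC is defined."""


@dataclass
class RocResult:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_variance: float
    n_cases: int
    n_controls: int

    def tpr_at_fpr(self, fpr: float) -> float:
        """Step-function TPR at a given FPR (highest TPR achieved at
        empirical FPR <= the requested one, i.e. the attainable operating
        point)."""
        idx = np.searchsorted(self.fpr, fpr, side="right") - 1
        return float(self.tpr[max(idx, 0)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    method: str
    degenerate: bool = False

    def __iter__(self):
        return iter((self.auc_a, self.auc_b, self.z, self.p))

    def to_dict(self) -> dict:
        return {
            "auc_a": self.auc_a,
            "auc_b": self.auc_b,
            "z": self.z,
            "p": self.p,
            "method": self.method,
            "degenerate": self.degenerate,
        }


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        arr = arr == "case"
    return arr.astype(bool)


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Placement values (V10 per case, V01 per control) and the AUC, via
    midranks -- O(n log n)."""
    x, yneg = scores[y], scores[~y]
    m, n = len(x), len(yneg)
    if m == 0 or n == 0:
        raise SingleClassError("both classes required")
    all_scores = np.concatenate([x, yneg])
    r_all = rankdata(all_scores)
    r_x = rankdata(x)
    r_y = rankdata(yneg)
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_y) / m
    auc = float(v10.mean())
    return v10, v01, auc


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC with tied scores grouped; starts at (0,0), ends (1,1)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise SingleClassError("roc_curve requires both cases and controls")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    v10, v01, auc_mw = _delong_components(s, y)
    auc = float(_trapezoid_auc(fpr, tpr))
    return RocResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_variance=_delong_variance(v10, v01),
        n_cases=int(y.sum()),
        n_controls=int((~y).sum()),
    )


def delong_paired(scores_a, scores_b, labels) -> DelongResult:
    """DeLong test for two AI systems scoring the same exams.

    Two-sided p from the normal approximation, with the covariance of the
    paired structural components included.  Identical scores give a zero
    variance of the difference; reported as z=0, p=1 with a degenerate flag.
    """
    y = _as_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("paired test requires the same exams for both systems")
    v10a, v01a, auc_a = _delong_components(a, y)
    v10b, v01b, auc_b = _delong_components(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    if var_diff <= 0:
        return DelongResult(auc_a, auc_b, 0.0, 1.0, "delong_paired", degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2.0 * norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, float(z), p, "delong_paired")


def delong_unpaired(
    scores_a, labels_a, scores_b, labels_b, *, exam_ids_a=None, exam_ids_b=None
) -> DelongResult:
    """DeLong-variance z test for AUCs of two datasets (or subsets).

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b).  Passing exam ids enables an
    overlap check; overlapping ids violate the independence assumption and
    only produce a warning (the test is then conservative).
    """
    if exam_ids_a is not None and exam_ids_b is not None:
        overlap = set(exam_ids_a) & set(exam_ids_b)
        if overlap:
            warnings.warn(
                f"delong_unpaired: {len(overlap)} overlapping exam(s) between datasets; "
                "independence assumption violated (test is conservative)",
                stacklevel=2,
            )
    v10a, v01a, auc_a = _delong_components(
        np.asarray(scores_a, dtype=float), _as_binary(labels_a)
    )
    v10b, v01b, auc_b = _delong_components(
        np.asarray(scores_b, dtype=float), _as_binary(labels_b)
    )
    var = _delong_variance(v10a, v01a) + _delong_variance(v10b, v01b)
    if var <= 0:
        return DelongResult(auc_a, auc_b, 0.0, 1.0, "delong_unpaired", degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var)
    return DelongResult(auc_a, auc_b, float(z), float(2.0 * norm.sf(abs(z))), "delong_unpaired")
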