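"""ROC/AUC evaluation, median-ROC aggregation, Youden operating point and
the one-tailed Wilcoxon signed-rank test against chance.

AUC is the Mann-Whitney concordance probability with ties counted 1/2.
Repetition-level ROC curves are aggregated pointwise on a common
false-positive-rate grid using step-function interpolation (supremum of
the true-positive rate at fpr <= grid value), yielding a median curve with
25th/75th percentile bands.  The signed-rank test uses the exact null
distribution (sign-flip enumeration via dynamic programming, midranks for
tied magnitudes) up to n = 25 and a tie-corrected normal approximation
beyond.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "RocCurve",
    "MedianRoc",
    "OperatingPoint",
    "roc_and_auc",
    "median_roc",
    "youden_optimal",
    "wilcoxon_signed_rank",
    "wilcoxon_vs_chance",
    "summarize_auc",
    "EXACT_WILCOXON_MAX_N",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class RocCurve:
    """Ordered (fpr, tpr) pairs from (0, 0) to (1, 1)."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if fpr.shape != tpr.shape or fpr.ndim != 1:
            raise ValueError("fpr and tpr must be 1-D and equally long")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing")
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)


@dataclass(frozen=True)
class MedianRoc:
    """Pointwise median ROC with quartile bands on a common fpr grid."""

    fpr_grid: np.ndarray
    tpr_median: np.ndarray
    tpr_q25: np.ndarray
    tpr_q75: np.ndarray


@dataclass(frozen=True)
class OperatingPoint:
    fpr: float
    tpr: float

    @property
    def J(self) -> float:
        """Youden's index: sensitivity + specificity - 1 = tpr - fpr."""
        return self.tpr - self.fpr

    @property
    def sensitivity(self) -> float:
        return self.tpr

    @property
    def specificity(self) -> float:
        return 1.0 - self.fpr


def roc_and_auc(labels: Sequence[int], scores: Sequence[float]) -> tuple[RocCurve, float]:
    """ROC curve (full threshold sweep) and AUC for binary labels."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("one score per label required")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return RocCurve(fpr=fpr, tpr=tpr), auc


def _step_interp(curve: RocCurve, grid: np.ndarray) -> np.ndarray:
    # sup of tpr over curve points with fpr <= grid value; the epsilon
    # absorbs float noise between grid values and curve coordinates
    idx = np.searchsorted(curve.fpr, grid + 1e-9, side="right") - 1
    idx = np.clip(idx, 0, len(curve.fpr) - 1)
    # running maximum guards against locally non-monotone inputs
    tpr_max = np.maximum.accumulate(curve.tpr)
    return tpr_max[idx]


def median_roc(curves: Sequence[RocCurve], grid_step: float = 0.01) -> MedianRoc:
    """Pointwise median and quartiles of several ROC curves on a common grid."""
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 12)
    mat = np.stack([_step_interp(c, grid) for c in curves])
    q25, q50, q75 = np.percentile(mat, [25, 50, 75], axis=0)
    return MedianRoc(fpr_grid=grid, tpr_median=q50, tpr_q25=q25, tpr_q75=q75)


def youden_optimal(curve: RocCurve | MedianRoc) -> OperatingPoint:
    """Operating point maximizing J = tpr - fpr; ties broken by lower fpr."""
    if isinstance(curve, MedianRoc):
        fpr, tpr = curve.fpr_grid, curve.tpr_median
    else:
        fpr, tpr = curve.fpr, curve.tpr
    j = tpr - fpr
    best = int(np.argmax(j))  # first maximum = lowest fpr (fpr sorted ascending)
    return OperatingPoint(fpr=float(fpr[best]), tpr=float(tpr[best]))


def wilcoxon_signed_rank(diffs: Sequence[float], alternative: str = "greater") -> float:
    """One-sample Wilcoxon signed-rank p-value for the given differences.

    Zero differences are discarded; tied magnitudes receive midranks.  For
    n <= 25 the exact sign-flip null distribution is used (computed by
    dynamic programming over doubled ranks, which are integers even with
    midrank ties); otherwise a tie-corrected normal approximation.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    if alternative == "less":
        d = -d
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        r2 = np.rint(2 * ranks).astype(int)  # midranks doubled are integers
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts += shifted
        threshold = int(np.rint(2 * w_pos))
        return float(counts[threshold:].sum() / 2.0**n)
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    z = (w_pos - mu) / np.sqrt(sigma2)
    return float(stats.norm.sf(z))


def wilcoxon_vs_chance(aucs: Sequence[float], null: float = 0.5,
                       alternative: str = "greater") -> float:
    """One-tailed signed-rank test of repetition AUCs against chance level."""
    aucs = np.asarray(aucs, dtype=float)
    if len(aucs) < 5:
        raise ValueError("need at least 5 AUC values")
    return wilcoxon_signed_rank(aucs - null, alternative=alternative)


def summarize_auc(aucs: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Mean AUC and the empirical 90% CI (5th-95th percentiles) of repetitions."""
    aucs = np.asarray(aucs, dtype=float)
    if len(aucs) < 2:
        raise ValueError("need at least 2 AUC values")
    lo, hi = np.percentile(aucs, [5, 95])
    return float(aucs.mean()), (float(lo), float(hi))
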