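"""ROC curves, AUC and partial AUC from rating data.

A curve is built by cumulative thresholding: for each cutoff c (from the
most conservative response criterion to the most liberal), the
true-positive rate is P(score >= c | signal) and the false-positive rate
is P(score >= c | noise).  The trapezoidal area under the resulting
polyline equals the tie-corrected two-sample rank statistic
P(S > N) + 0.5 P(S = N), the probability that a randomly chosen signal
item outscores a randomly chosen noise item.

Score direction is fixed: higher scores are always more signal-like.
Estimates are never direction-flipped, so below-chance data yield
AUC < 0.5 rather than being silently corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import RatingData

__all__ = ["ROCCurve", "compute_roc", "auc", "partial_auc", "rank_auc"]


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) points with their rating cutoffs.

    ``thresholds`` run from the most conservative cutoff (highest rating)
    to the most liberal; anchor points (0, 0) and (1, 1) are prepended and
    appended, so ``len(fpr) == len(thresholds) + 2``.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        fpr, tpr = np.asarray(self.fpr, float), np.asarray(self.tpr, float)
        if fpr.size != tpr.size or fpr.size != self.thresholds.size + 2:
            raise ValueError("curve must carry one point per threshold plus two anchors")
        if (np.diff(fpr) < 0).any() or (np.diff(tpr) < 0).any():
            raise ValueError("FPR and TPR must be non-decreasing along the curve")
        if fpr[0] != 0 or tpr[0] != 0 or fpr[-1] != 1 or tpr[-1] != 1:
            raise ValueError("curve must start at (0,0) and end at (1,1)")

    def to_frame(self):
        import pandas as pd

        thr = np.concatenate([[np.inf], self.thresholds, [-np.inf]])
        return pd.DataFrame({"threshold": thr, "fpr": self.fpr, "tpr": self.tpr})


def compute_roc(data: RatingData) -> ROCCurve:
    """Build the empirical ROC curve of a rating dataset.

    Cutoffs are the distinct observed scores in descending order; each
    point is (P(score >= c | noise), P(score >= c | signal)).
    """
    cutoffs = np.unique(data.scores)[::-1]
    if cutoffs.size == 1:
        warnings.warn("all scores identical: no discrimination information", stacklevel=2)
    sig = np.sort(data.signal_scores)
    noi = np.sort(data.noise_scores)
    m, n = sig.size, noi.size
    # P(score >= c) via positions in the sorted per-class arrays
    tpr = 1.0 - np.searchsorted(sig, cutoffs, side="left") / m
    fpr = 1.0 - np.searchsorted(noi, cutoffs, side="left") / n
    return ROCCurve(
        thresholds=cutoffs,
        fpr=np.concatenate([[0.0], fpr, [1.0]]),
        tpr=np.concatenate([[0.0], tpr, [1.0]]),
    )


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the (FPR, TPR) polyline."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def rank_auc(data: RatingData) -> float:
    """AUC as the tie-corrected Mann-Whitney statistic.

    Equals ``auc(compute_roc(data))`` exactly; exposed as an independent
    route for cross-checks and as the estimate the DeLong machinery uses.
    """
    m, n = data.n_signal, data.n_noise
    ranks = rankdata(np.concatenate([data.signal_scores, data.noise_scores]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def partial_auc(curve: ROCCurve, fpr_lo: float, fpr_hi: float) -> float:
    """Raw (un-standardized) area of the curve restricted to an FPR range.

    TPR is linearly interpolated where a range boundary falls between
    observed points.  Additive over adjacent ranges; ``[0, 1]`` recovers
    the full AUC.
    """
    if not (0.0 <= fpr_lo < fpr_hi <= 1.0):
        raise ValueError("need 0 <= fpr_lo < fpr_hi <= 1")
    x, y = curve.fpr, curve.tpr
    area = 0.0
    for i in range(x.size - 1):
        x0, x1 = x[i], x[i + 1]
        a, b = max(x0, fpr_lo), min(x1, fpr_hi)
        if a >= b or x1 == x0:  # outside range, or vertical segment (zero area)
            continue
        slope = (y[i + 1] - y[i]) / (x1 - x0)
        ya = y[i] + slope * (a - x0)
        yb = y[i] + slope * (b - x0)
        area += 0.5 * (ya + yb) * (b - a)
    return float(area)
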