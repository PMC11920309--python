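"""Variance estimation and confidence intervals for AUC, pAUC and ΔAUC.

Full-curve estimates use the DeLong placement-value estimator (midrank
formulation): each signal observation gets the fraction of noise
observations it beats (ties count one half), and vice versa; the AUC
variance is the sum of the two placement sample variances scaled by the
class sizes.  Partial-AUC estimates use a stratified percentile bootstrap,
resampling cases and controls separately so class sizes are preserved.

Wald intervals are deliberately left unclamped: decision rules (notably
equivalence tests near a boundary) operate on the raw bounds, and clamping
would bias them.  The 95%/90% z quantiles are fixed at 1.96 and 1.645 at
alpha = 0.05, matching the conventional interval formula; other alpha
levels fall back to the exact normal quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import norm, rankdata

from .data import DegenerateDataError, RatingData
from .roc import compute_roc, partial_auc, rank_auc

__all__ = [
    "AUCEstimate",
    "DeltaAUCEstimate",
    "delong_components",
    "auc_ci",
    "unpaired_delta_ci",
    "paired_delta_ci",
    "bootstrap_pauc_ci",
]

_Z = {0.95: 1.96, 0.90: 1.645}


def z_quantile(conf: float) -> float:
    """Two-sided normal quantile; fixed 1.96/1.645 at the 95%/90% levels."""
    return _Z.get(round(conf, 6), float(norm.ppf(0.5 + conf / 2)))


@dataclass(frozen=True)
class AUCEstimate:
    """Point estimate with variance and Wald or percentile intervals."""

    auc: float
    variance: float
    ci95: tuple[float, float]
    ci90: tuple[float, float]
    method: str  # "delong" | "bootstrap"
    fpr_range: tuple[float, float] | None = None
    degenerate: bool = False
    n_boot: int | None = None
    seed: int | None = None

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "ci95": list(self.ci95),
            "ci90": list(self.ci90),
            "method": self.method,
            "fpr_range": list(self.fpr_range) if self.fpr_range else None,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class DeltaAUCEstimate:
    """Difference of two AUCs (or pAUCs) with its standard error and CIs."""

    delta: float
    se: float
    ci95: tuple[float, float]
    ci90: tuple[float, float]
    design: str  # "paired" | "unpaired"
    method: str = "delong"
    fpr_range: tuple[float, float] | None = None
    degenerate: bool = False
    n_boot: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "se": self.se,
            "ci95": list(self.ci95),
            "ci90": list(self.ci90),
            "design": self.design,
            "method": self.method,
            "fpr_range": list(self.fpr_range) if self.fpr_range else None,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


class DelongResult(NamedTuple):
    auc: float
    variance: float


def _placements(data: RatingData) -> tuple[np.ndarray, np.ndarray]:
    """Midrank placement values V10 (per signal obs) and V01 (per noise obs)."""
    x, y = data.signal_scores, data.noise_scores
    m, n = x.size, y.size
    overall = rankdata(np.concatenate([x, y]))
    v10 = (overall[:m] - rankdata(x)) / n
    v01 = 1.0 - (overall[m:] - rankdata(y)) / m
    return v10, v01


def delong_components(data: RatingData) -> DelongResult:
    """DeLong AUC and variance from placement values.

    The AUC is the mean signal placement and equals the tie-corrected rank
    statistic exactly.  Sample variances use denominator (count - 1).
    """
    m, n = data.n_signal, data.n_noise
    if m < 2 or n < 2:
        raise DegenerateDataError("DeLong variance needs at least 2 observations per class")
    v10, v01 = _placements(data)
    # point estimate via the rank statistic: identical math to v10.mean()
    # but bit-for-bit equal to the ROC-module AUC
    auc = rank_auc(data)
    variance = float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)
    return DelongResult(auc=auc, variance=variance)


def _wald(center: float, se: float, conf: float) -> tuple[float, float]:
    z = z_quantile(conf)
    return (center - z * se, center + z * se)


def auc_ci(
    data: RatingData,
    method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
    fpr_range: tuple[float, float] | None = None,
) -> AUCEstimate:
    """AUC estimate with (1-alpha) and (1-2*alpha) confidence intervals.

    ``method="delong"`` gives Wald intervals from the placement variance;
    ``method="bootstrap"`` gives stratified percentile intervals (required
    for partial ranges).
    """
    if method == "bootstrap" or fpr_range is not None:
        return bootstrap_pauc_ci(
            data, fpr_range=fpr_range or (0.0, 1.0), n_boot=n_boot, alpha=alpha, seed=seed
        )
    est, var = delong_components(data)
    se = float(np.sqrt(var))
    return AUCEstimate(
        auc=est,
        variance=var,
        ci95=_wald(est, se, 1 - alpha),
        ci90=_wald(est, se, 1 - 2 * alpha),
        method="delong",
        degenerate=var == 0.0,
    )


def unpaired_delta_ci(
    data1: RatingData, data2: RatingData, alpha: float = 0.05
) -> DeltaAUCEstimate:
    """ΔAUC = AUC1 - AUC2 for two independent groups.

    The SE is sqrt(V1 + V2) from each group's DeLong variance — the same
    algebra as deriving it from the unpaired DeLong z statistic, but well
    defined when the difference is exactly zero.
    """
    a1, v1 = delong_components(data1)
    a2, v2 = delong_components(data2)
    delta = a1 - a2
    se = float(np.sqrt(v1 + v2))
    return DeltaAUCEstimate(
        delta=delta,
        se=se,
        ci95=_wald(delta, se, 1 - alpha),
        ci90=_wald(delta, se, 1 - 2 * alpha),
        design="unpaired",
        degenerate=se == 0.0,
    )


def paired_delta_ci(
    data_cond1: RatingData, data_cond2: RatingData, alpha: float = 0.05
) -> DeltaAUCEstimate:
    """ΔAUC for two paired conditions measured on the same items.

    Var(Δ) = V1 + V2 - 2 Cov(A1, A2); the covariance comes from the paired
    placement components, aligned by ``pairing_id``.
    """
    if data_cond1.pairing_id is None or data_cond2.pairing_id is None:
        raise ValueError("paired comparison requires pairing_id on both conditions")
    d1 = _sort_by_pairing(data_cond1)
    d2 = _sort_by_pairing(data_cond2)
    for cls in (1, 0):
        ids1 = d1.pairing_id[d1.labels == cls]
        ids2 = d2.pairing_id[d2.labels == cls]
        if ids1.size != ids2.size or not np.array_equal(ids1, ids2):
            raise ValueError("pairing_id must link conditions one-to-one within each class")
    m, n = d1.n_signal, d1.n_noise
    if m < 2 or n < 2:
        raise DegenerateDataError("DeLong variance needs at least 2 observations per class")
    v10_1, v01_1 = _placements(d1)
    v10_2, v01_2 = _placements(d2)
    a1, a2 = rank_auc(d1), rank_auc(d2)
    var1 = v10_1.var(ddof=1) / m + v01_1.var(ddof=1) / n
    var2 = v10_2.var(ddof=1) / m + v01_2.var(ddof=1) / n
    cov = (
        np.cov(v10_1, v10_2, ddof=1)[0, 1] / m
        + np.cov(v01_1, v01_2, ddof=1)[0, 1] / n
    )
    var_delta = max(var1 + var2 - 2 * cov, 0.0)
    delta, se = a1 - a2, float(np.sqrt(var_delta))
    return DeltaAUCEstimate(
        delta=delta,
        se=se,
        ci95=_wald(delta, se, 1 - alpha),
        ci90=_wald(delta, se, 1 - 2 * alpha),
        design="paired",
        degenerate=se == 0.0,
    )


def _sort_by_pairing(data: RatingData) -> RatingData:
    # stable sort: signal block first, by pairing id within class
    order = np.lexsort((data.pairing_id, -data.labels))
    return RatingData(
        labels=data.labels[order],
        scores=data.scores[order],
        participant_id=None if data.participant_id is None else data.participant_id[order],
        pairing_id=data.pairing_id[order],
        group_id=data.group_id,
    )


def _pauc_of(labels_sig: np.ndarray, labels_noi: np.ndarray, lo: float, hi: float) -> float:
    data = RatingData(
        labels=np.concatenate(
            [np.ones(labels_sig.size, dtype=np.int8), np.zeros(labels_noi.size, dtype=np.int8)]
        ),
        scores=np.concatenate([labels_sig, labels_noi]),
    )
    return partial_auc(compute_roc(data), lo, hi)


def bootstrap_pauc_ci(
    data: RatingData,
    data2: RatingData | None = None,
    fpr_range: tuple[float, float] = (0.0, 1.0),
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> AUCEstimate | DeltaAUCEstimate:
    """Stratified percentile-bootstrap CI for a pAUC or a pAUC difference.

    Cases and controls are resampled separately within each group, so
    every replicate keeps the original class sizes.  With ``data2`` the
    statistic is pAUC1 - pAUC2 for two independent groups.  Reproducible
    given ``seed``.
    """
    lo, hi = fpr_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("fpr_range must satisfy 0 <= lo < hi <= 1")
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    rng = np.random.default_rng(seed)

    groups = [(data.signal_scores, data.noise_scores)]
    if data2 is not None:
        groups.append((data2.signal_scores, data2.noise_scores))

    point = _pauc_of(groups[0][0], groups[0][1], lo, hi)
    if data2 is not None:
        point -= _pauc_of(groups[1][0], groups[1][1], lo, hi)

    reps = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            stat = 0.0
            sign = 1.0
            for sig, noi in groups:
                rs = rng.choice(sig, size=sig.size, replace=True)
                rn = rng.choice(noi, size=noi.size, replace=True)
                stat += sign * _pauc_of(rs, rn, lo, hi)
                sign = -1.0
            if np.isfinite(stat):
                break
            n_redrawn += 1  # pragma: no cover - stratified replicates stay valid
        reps[b] = stat

    q = np.quantile(reps, [alpha / 2, 1 - alpha / 2, alpha, 1 - alpha])
    ci95, ci90 = (float(q[0]), float(q[1])), (float(q[2]), float(q[3]))
    var = float(reps.var(ddof=1))
    if data2 is None:
        return AUCEstimate(
            auc=point,
            variance=var,
            ci95=ci95,
            ci90=ci90,
            method="bootstrap",
            fpr_range=(lo, hi),
            degenerate=var == 0.0,
            n_boot=n_boot,
            seed=seed,
        )
    return DeltaAUCEstimate(
        delta=point,
        se=float(np.sqrt(var)),
        ci95=ci95,
        ci90=ci90,
        design="unpaired",
        method="bootstrap",
        fpr_range=(lo, hi),
        degenerate=var == 0.0,
        n_boot=n_boot,
        seed=seed,
    )
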