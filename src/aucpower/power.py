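"""Confidence-interval-focused decision rules and the power simulation loop.

Three hypothesis tests are evaluated per simulated dataset, all phrased as
conditions on confidence intervals:

* NHST — the 95% CI excludes the null value (0.5 for a single AUC, 0 for
  an AUC difference).
* Minimum-effect test (MET) — the entire 95% CI lies beyond the smallest
  effect size of interest (SESOI) in the hypothesized direction.
* Equivalence test (TOST via 90% CI) — the 90% CI lies strictly inside
  the equivalence region set by the SESOI: (1-SESOI, SESOI) around 0.5
  for a single AUC, (-SESOI, +SESOI) for a difference.

Power for each test is the fraction of simulated datasets on which the
decision fires.  Datasets whose estimate is degenerate (a single-valued
class or zero DeLong variance) count as failures for all three tests and
are tallied, never silently dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .data import DegenerateDataError
from .datagen import BinormalSpec, closed_form_auc, generate_paired_ratings, generate_ratings
from .inference import (
    AUCEstimate,
    DeltaAUCEstimate,
    auc_ci,
    bootstrap_pauc_ci,
    paired_delta_ci,
    unpaired_delta_ci,
)

__all__ = [
    "PowerConfig",
    "PowerReport",
    "decide_nhst",
    "decide_met",
    "decide_eq",
    "run_power",
    "type1_check",
]

_DESIGNS = ("single", "two_unpaired", "two_paired")


@dataclass(frozen=True)
class PowerConfig:
    """Complete specification of one power simulation run."""

    design: str
    spec1: BinormalSpec
    spec2: BinormalSpec | None = None
    sesoi: float | None = None
    alpha: float = 0.05
    n_sims: int = 1000
    seed: int = 0
    fpr_range: tuple[float, float] | None = None
    n_boot: int | None = None

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise ValueError(f"design must be one of {_DESIGNS}")
        if self.design != "single" and self.spec2 is None:
            raise ValueError("two-group designs require spec2")
        if self.design == "single" and self.spec2 is not None:
            raise ValueError("single design takes no spec2")
        if self.sesoi is not None:
            if self.design == "single" and not 0.5 < self.sesoi < 1.0:
                raise ValueError("single-curve SESOI must be an AUC in (0.5, 1)")
            if self.design != "single" and not 0.0 < self.sesoi <= 0.5:
                raise ValueError("two-group SESOI must be a ΔAUC in (0, 0.5]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")
        if self.fpr_range is not None:
            if self.design == "single":
                raise ValueError("partial-AUC power runs compare two groups")
            lo, hi = self.fpr_range
            if not 0.0 <= lo < hi <= 1.0:
                raise ValueError("fpr_range must satisfy 0 <= lo < hi <= 1")

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "spec1": self.spec1.to_dict(),
            "spec2": self.spec2.to_dict() if self.spec2 else None,
            "sesoi": self.sesoi,
            "alpha": self.alpha,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "fpr_range": list(self.fpr_range) if self.fpr_range else None,
            "n_boot": self.n_boot,
        }


@dataclass(frozen=True)
class PowerReport:
    """Estimated power per test with its Monte-Carlo standard error."""

    power_nhst: float
    power_met: float | None
    power_eq: float | None
    mc_se: dict
    n_sims: int
    n_degenerate: int
    config: PowerConfig
    seed: int

    def to_dict(self) -> dict:
        return {
            "power_nhst": self.power_nhst,
            "power_met": self.power_met,
            "power_eq": self.power_eq,
            "mc_se": self.mc_se,
            "n_sims": self.n_sims,
            "n_degenerate": self.n_degenerate,
            "seed": self.seed,
            "config": self.config.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_table(self) -> str:
        rows = [
            ("Null-hypothesis significance test", self.power_nhst, self.mc_se["nhst"]),
            ("Minimum-effect test", self.power_met, self.mc_se.get("met")),
            ("Equivalence test", self.power_eq, self.mc_se.get("eq")),
        ]
        lines = [f"{'Test':<36}{'Power':>8}{'MC SE':>9}"]
        for name, p, se in rows:
            if p is None:
                lines.append(f"{name:<36}{'—':>8}{'—':>9}")
            else:
                lines.append(f"{name:<36}{p:>8.3f}{se:>9.3f}")
        lines.append(
            f"(n_sims = {self.n_sims}, degenerate datasets = {self.n_degenerate}, "
            f"seed = {self.seed})"
        )
        return "\n".join(lines)


def decide_nhst(est: AUCEstimate | DeltaAUCEstimate) -> bool:
    """True iff the 95% CI excludes the null (0.5 for AUC, 0 for ΔAUC)."""
    if est.degenerate:
        return False
    null = 0.5 if isinstance(est, AUCEstimate) else 0.0
    lo, hi = est.ci95
    return bool(lo > null or hi < null)


def decide_met(est: AUCEstimate | DeltaAUCEstimate, sesoi: float) -> bool:
    """True iff the whole 95% CI lies beyond the SESOI in the
    hypothesized-positive direction (lower bound above the SESOI)."""
    if est.degenerate:
        return False
    return bool(est.ci95[0] > sesoi)


def decide_eq(est: AUCEstimate | DeltaAUCEstimate, sesoi: float) -> bool:
    """True iff the 90% CI lies strictly inside the equivalence region."""
    if est.degenerate:
        return False
    if isinstance(est, AUCEstimate):
        lo_bound, hi_bound = 1.0 - sesoi, sesoi
    else:
        lo_bound, hi_bound = -sesoi, sesoi
    lo, hi = est.ci90
    return bool(lo > lo_bound and hi < hi_bound)


def _one_estimate(config: PowerConfig, child: np.random.SeedSequence):
    """Generate one dataset (or pair of groups) and estimate its effect.

    For two-group designs the difference is oriented so the
    hypothesized-larger group (by the continuous binormal truth) comes
    first, making the MET direction well defined.
    """
    rng = np.random.default_rng(child)
    if config.design == "single":
        data = generate_ratings(config.spec1, rng)
        return auc_ci(data, alpha=config.alpha)

    flip = closed_form_auc(config.spec2) > closed_form_auc(config.spec1)
    if config.design == "two_paired":
        d1, d2 = generate_paired_ratings(config.spec1, config.spec2, rng)
    else:
        d1 = generate_ratings(config.spec1, rng)
        d2 = generate_ratings(config.spec2, rng)
    hi_grp, lo_grp = (d2, d1) if flip else (d1, d2)

    if config.fpr_range is not None:
        return bootstrap_pauc_ci(
            hi_grp,
            lo_grp,
            fpr_range=config.fpr_range,
            n_boot=config.n_boot or 500,
            alpha=config.alpha,
            seed=rng,
        )
    if config.design == "two_paired":
        return paired_delta_ci(hi_grp, lo_grp, alpha=config.alpha)
    return unpaired_delta_ci(hi_grp, lo_grp, alpha=config.alpha)


def run_power(config: PowerConfig) -> PowerReport:
    """Run the full simulation loop and estimate power for all three tests.

    A master SeedSequence spawns one independent substream per simulated
    dataset, so runs are reproducible and order-independent.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_sims)
    n_nhst = n_met = n_eq = n_degenerate = 0
    for child in children:
        try:
            est = _one_estimate(config, child)
        except DegenerateDataError:
            n_degenerate += 1
            continue
        if est.degenerate:
            n_degenerate += 1
            continue
        n_nhst += decide_nhst(est)
        if config.sesoi is not None:
            n_met += decide_met(est, config.sesoi)
            n_eq += decide_eq(est, config.sesoi)

    n = config.n_sims

    def _mc_se(p: float) -> float:
        return math.sqrt(p * (1 - p) / n)

    p_nhst = n_nhst / n
    mc = {"nhst": _mc_se(p_nhst)}
    p_met = p_eq = None
    if config.sesoi is not None:
        p_met, p_eq = n_met / n, n_eq / n
        mc["met"], mc["eq"] = _mc_se(p_met), _mc_se(p_eq)
    return PowerReport(
        power_nhst=p_nhst,
        power_met=p_met,
        power_eq=p_eq,
        mc_se=mc,
        n_sims=n,
        n_degenerate=n_degenerate,
        config=config,
        seed=config.seed,
    )


def type1_check(config: PowerConfig, test: str = "nhst") -> float:
    """Rejection/pass rate of one test under a boundary-true configuration.

    Intended for calibration: run with the true effect placed exactly at
    the null (NHST) or at the SESOI (MET, EQ) and read off the rate.
    """
    report = run_power(config)
    rate = {"nhst": report.power_nhst, "met": report.power_met, "eq": report.power_eq}[test]
    if rate is None:
        raise ValueError(f"test {test!r} needs a SESOI in the config")
    return rate
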