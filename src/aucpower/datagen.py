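"""Binormal rating-data generator.

The data-generating process is the classic signal-detection model: latent
strengths are normal, N(mu_noise, sd_noise) for noise items and
N(mu_signal, sd_signal) for signal items.  In the equal-variance case the
continuous AUC is Phi((mu_signal - mu_noise) / sqrt(2)), so a signal mean
of 0.38 corresponds to an AUC of about 0.60 and 0.78 to about 0.71.

Latent values are then redistributed onto a discrete 1..K confidence
scale.  The default rule bins the pooled latent values of a dataset into
K equal-count (quantile) bins, which leaves the AUC nearly unchanged by
discretization; an equal-width alternative over the pooled [min, max] is
available via ``rule="equal_width"`` and attenuates the AUC noticeably
more.  See docs/methods.md for the comparison.

Paired designs draw the two conditions' latent values from a bivariate
normal with correlation ``rho``, applied to signal and noise items alike.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .data import RatingData
from .roc import rank_auc

__all__ = [
    "BinormalSpec",
    "closed_form_auc",
    "discretize",
    "generate_ratings",
    "generate_paired_ratings",
    "estimate_auc_empirical",
]


@dataclass(frozen=True)
class BinormalSpec:
    """Parameters of one group's binormal rating experiment.

    Defaults mirror a typical confidence-rating recognition study: noise
    mean 0, unit SDs, a 6-point scale, 100 participants rating 2 signal
    and 2 noise items each.
    """

    mu_signal: float
    mu_noise: float = 0.0
    sd_signal: float = 1.0
    sd_noise: float = 1.0
    k_levels: int = 6
    n_participants: int = 100
    items_signal: int = 2
    items_noise: int = 2
    rho: float = 0.0
    continuous: bool = False
    disc_rule: str = "quantile"  # or "equal_width"

    def __post_init__(self) -> None:
        if self.sd_signal <= 0 or self.sd_noise <= 0:
            raise ValueError("standard deviations must be positive")
        if self.k_levels < 2:
            raise ValueError("need at least 2 rating levels")
        if min(self.n_participants, self.items_signal, self.items_noise) < 1:
            raise ValueError("participant and item counts must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        if self.disc_rule not in ("quantile", "equal_width"):
            raise ValueError("disc_rule must be 'quantile' or 'equal_width'")

    @property
    def n_signal_total(self) -> int:
        return self.n_participants * self.items_signal

    @property
    def n_noise_total(self) -> int:
        return self.n_participants * self.items_noise

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def closed_form_auc(spec: BinormalSpec) -> float:
    """Continuous binormal AUC: Phi(dmu / sqrt(sd_s^2 + sd_n^2))."""
    dmu = spec.mu_signal - spec.mu_noise
    return float(norm.cdf(dmu / np.hypot(spec.sd_signal, spec.sd_noise)))


def discretize(values: np.ndarray, k_levels: int, rule: str = "quantile") -> np.ndarray:
    """Redistribute continuous values onto an ordinal 1..K scale.

    ``"quantile"`` splits the pooled values into K equal-count bins;
    ``"equal_width"`` splits the pooled [min, max] into K equal-width
    intervals.  Both are per-dataset rules: the cutpoints come from the
    values themselves.
    """
    values = np.asarray(values, float)
    if rule == "quantile":
        edges = np.quantile(values, np.linspace(0, 1, k_levels + 1)[1:-1])
    elif rule == "equal_width":
        edges = np.linspace(values.min(), values.max(), k_levels + 1)[1:-1]
    else:
        raise ValueError(f"unknown discretization rule: {rule!r}")
    return (np.digitize(values, edges) + 1).astype(float)


def _participant_ids(spec: BinormalSpec) -> np.ndarray:
    return np.concatenate(
        [
            np.repeat(np.arange(spec.n_participants), spec.items_signal),
            np.repeat(np.arange(spec.n_participants), spec.items_noise),
        ]
    )


def _labels(m: int, n: int) -> np.ndarray:
    return np.concatenate([np.ones(m, dtype=np.int8), np.zeros(n, dtype=np.int8)])


def generate_ratings(spec: BinormalSpec, rng_seed) -> RatingData:
    """Draw one rating dataset from the binormal model.

    ``rng_seed`` may be an int, a SeedSequence or a Generator; the same
    seed always yields the identical dataset.  Participant structure is
    recorded but observations are generated independently.
    """
    rng = np.random.default_rng(rng_seed)
    m, n = spec.n_signal_total, spec.n_noise_total
    latent = np.concatenate(
        [
            rng.normal(spec.mu_signal, spec.sd_signal, m),
            rng.normal(spec.mu_noise, spec.sd_noise, n),
        ]
    )
    scores = latent if spec.continuous else discretize(latent, spec.k_levels, spec.disc_rule)
    return RatingData(
        labels=_labels(m, n),
        scores=scores,
        participant_id=_participant_ids(spec),
    )


def generate_paired_ratings(
    spec1: BinormalSpec, spec2: BinormalSpec, rng_seed
) -> tuple[RatingData, RatingData]:
    """Draw two paired conditions with latent correlation ``spec1.rho``.

    Both conditions share the item layout; each observation in condition 1
    is linked to its counterpart in condition 2 through ``pairing_id``.
    Each condition is discretized separately.
    """
    if (spec1.n_participants, spec1.items_signal, spec1.items_noise) != (
        spec2.n_participants,
        spec2.items_signal,
        spec2.items_noise,
    ):
        raise ValueError("paired conditions must share the participant/item layout")
    rng = np.random.default_rng(rng_seed)
    rho = spec1.rho
    m, n = spec1.n_signal_total, spec1.n_noise_total
    z1 = rng.standard_normal(m + n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(m + n)

    out = []
    pairing = np.arange(m + n)
    for spec, z in ((spec1, z1), (spec2, z2)):
        latent = np.concatenate(
            [
                spec.mu_signal + spec.sd_signal * z[:m],
                spec.mu_noise + spec.sd_noise * z[m:],
            ]
        )
        scores = latent if spec.continuous else discretize(latent, spec.k_levels, spec.disc_rule)
        out.append(
            RatingData(
                labels=_labels(m, n),
                scores=scores,
                participant_id=_participant_ids(spec),
                pairing_id=pairing,
            )
        )
    return out[0], out[1]


def estimate_auc_empirical(spec: BinormalSpec, n_items: int = 10_000, rng_seed=None) -> float:
    """Empirical AUC of one large generated sample (n_items per class).

    Mirrors estimating the AUC implied by a parameter set from a single
    precise simulation; participant structure is collapsed.
    """
    if n_items < 1000:
        raise ValueError("n_items must be at least 1000 for a stable estimate")
    big = replace(spec, n_participants=1, items_signal=n_items, items_noise=n_items)
    return rank_auc(generate_ratings(big, rng_seed))
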