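"""Built-in example dataset.

A hypothetical two-group recognition-memory experiment: 100 participants
per group (alcohol vs placebo) each rate 10 studied ("old", signal) and
10 non-studied ("new", noise) items on a 6-point confidence scale, giving
1000 ratings per class per group.  The counts are the classic worked
example for rating-based ROC analysis: the alcohol group discriminates
worse (AUC 0.61) than the placebo group (AUC 0.73).
"""

from __future__ import annotations

from .data import FrequencyTable

__all__ = ["CONFIDENCE_LEVELS", "alcohol_placebo_example"]

CONFIDENCE_LEVELS: tuple[str, ...] = (
    "Very confident new",
    "Somewhat confident new",
    "Not sure - new",
    "Not sure - old",
    "Somewhat confident old",
    "Very confident old",
)


def alcohol_placebo_example() -> dict[str, FrequencyTable]:
    """Frequency tables for the alcohol and placebo groups."""
    return {
        "alcohol": FrequencyTable(
            group_id="alcohol",
            levels=CONFIDENCE_LEVELS,
            signal_counts=(100, 150, 300, 100, 200, 150),
            noise_counts=(300, 200, 100, 150, 150, 100),
        ),
        "placebo": FrequencyTable(
            group_id="placebo",
            levels=CONFIDENCE_LEVELS,
            signal_counts=(50, 100, 350, 150, 250, 100),
            noise_counts=(350, 250, 150, 100, 100, 50),
        ),
    }
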