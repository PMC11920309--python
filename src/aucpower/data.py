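"""Containers for confidence-rating data.

Two representations are supported: per-group frequency tables (counts of
signal and noise items at each confidence level, the shape in which
recognition-memory data are usually tabulated) and expanded
observation-level rating data (one row per rated item).  Frequency tables
expand losslessly to rating data and rating data with integer scores
re-tabulate losslessly back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyTable",
    "RatingData",
    "DegenerateDataError",
    "expand_frequency_table",
    "tabulate",
    "read_frequency_tables",
    "read_rating_data",
    "write_rating_data",
]


class DegenerateDataError(ValueError):
    """Raised when data cannot support the requested estimate
    (e.g. a class with fewer than two observations for a DeLong variance)."""


@dataclass(frozen=True)
class FrequencyTable:
    """Counts of signal and noise items per confidence level for one group.

    Levels are ordered from the most "noise-like" response (e.g. *very
    confident new*) to the most "signal-like" (*very confident old*), so
    level index ``i`` corresponds to rating ``i + 1`` on a 1..K scale.
    """

    group_id: str
    levels: tuple[str, ...]
    signal_counts: tuple[int, ...]
    noise_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.levels)
        if k < 2:
            raise ValueError("need at least two confidence levels")
        if len(self.signal_counts) != k or len(self.noise_counts) != k:
            raise ValueError("count vectors must match the number of levels")
        counts = self.signal_counts + self.noise_counts
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if sum(self.signal_counts) < 1 or sum(self.noise_counts) < 1:
            raise DegenerateDataError("degenerate table: empty class")

    @property
    def n_signal(self) -> int:
        return int(sum(self.signal_counts))

    @property
    def n_noise(self) -> int:
        return int(sum(self.noise_counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_id,
                "level_index": np.arange(1, len(self.levels) + 1),
                "level": list(self.levels),
                "signal_count": list(self.signal_counts),
                "noise_count": list(self.noise_counts),
            }
        )


@dataclass
class RatingData:
    """Observation-level labels and scores.

    ``labels`` are 1 for signal (old/studied) items and 0 for noise (new)
    items; ``scores`` are ordinal confidence ratings in 1..K or continuous
    values, with higher scores always meaning "more signal-like".
    ``pairing_id`` links observations across two paired conditions.
    """

    labels: np.ndarray
    scores: np.ndarray
    participant_id: np.ndarray | None = None
    pairing_id: np.ndarray | None = None
    group_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.shape != self.scores.shape or self.labels.ndim != 1:
            raise ValueError("labels and scores must be 1-D and equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (noise) or 1 (signal)")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if self.n_signal == 0 or self.n_noise == 0:
            raise DegenerateDataError("need at least one observation per class")
        for name in ("participant_id", "pairing_id"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.labels.shape:
                    raise ValueError(f"{name} must match the number of observations")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_signal(self) -> int:
        return int(self.labels.sum())

    @property
    def n_noise(self) -> int:
        return int(self.labels.size - self.labels.sum())

    @property
    def signal_scores(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    @property
    def noise_scores(self) -> np.ndarray:
        return self.scores[self.labels == 0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"label": self.labels, "rating": self.scores})
        df.insert(0, "group", self.group_id)
        df.insert(
            1,
            "participant",
            self.participant_id if self.participant_id is not None else -1,
        )
        return df


def expand_frequency_table(table: FrequencyTable) -> RatingData:
    """Expand per-level counts into one observation per rated item.

    Ratings are the 1-based level indices; the expansion preserves every
    cell count exactly and is the inverse of re-tabulating.
    """
    k = len(table.levels)
    ratings = np.arange(1, k + 1)
    scores = np.concatenate(
        [np.repeat(ratings, table.signal_counts), np.repeat(ratings, table.noise_counts)]
    )
    labels = np.concatenate(
        [np.ones(table.n_signal, dtype=np.int8), np.zeros(table.n_noise, dtype=np.int8)]
    )
    return RatingData(labels=labels, scores=scores.astype(float), group_id=table.group_id)


def tabulate(data: RatingData, k_levels: int, levels: tuple[str, ...] | None = None) -> FrequencyTable:
    """Re-tabulate integer-scored rating data into a frequency table."""
    scores = data.scores.astype(int)
    if not np.array_equal(scores, data.scores) or scores.min() < 1 or scores.max() > k_levels:
        raise ValueError("scores must be integer ratings in 1..k_levels")
    if levels is None:
        levels = tuple(str(i) for i in range(1, k_levels + 1))
    bins = np.arange(1, k_levels + 2)
    sig, _ = np.histogram(scores[data.labels == 1], bins=bins)
    noi, _ = np.histogram(scores[data.labels == 0], bins=bins)
    return FrequencyTable(
        group_id=data.group_id,
        levels=levels,
        signal_counts=tuple(int(c) for c in sig),
        noise_counts=tuple(int(c) for c in noi),
    )


def read_frequency_tables(path) -> dict[str, FrequencyTable]:
    """Read frequency tables from CSV with columns
    ``group, level_index, signal_count, noise_count`` (optional ``level``)."""
    df = pd.read_csv(path)
    tables: dict[str, FrequencyTable] = {}
    for group, sub in df.groupby("group", sort=False):
        sub = sub.sort_values("level_index")
        levels = (
            tuple(sub["level"].astype(str))
            if "level" in sub
            else tuple(str(i) for i in sub["level_index"])
        )
        tables[str(group)] = FrequencyTable(
            group_id=str(group),
            levels=levels,
            signal_counts=tuple(int(c) for c in sub["signal_count"]),
            noise_counts=tuple(int(c) for c in sub["noise_count"]),
        )
    return tables


def read_rating_data(path) -> dict[str, RatingData]:
    """Read rating data from CSV with columns ``group, participant, label, rating``."""
    df = pd.read_csv(path)
    out: dict[str, RatingData] = {}
    for group, sub in df.groupby("group", sort=False):
        out[str(group)] = RatingData(
            labels=sub["label"].to_numpy(),
            scores=sub["rating"].to_numpy(dtype=float),
            participant_id=sub["participant"].to_numpy() if "participant" in sub else None,
            group_id=str(group),
        )
    return out


def write_rating_data(data: RatingData, path) -> None:
    data.to_frame().to_csv(path, index=False)
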