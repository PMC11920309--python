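import numpy as np
import pytest

import aucpower as ap


@pytest.fixture(scope="session")
def example_tables():
    return ap.alcohol_placebo_example()


@pytest.fixture(scope="session")
def alcohol(example_tables):
    return ap.expand_frequency_table(example_tables["alcohol"])


@pytest.fixture(scope="session")
def placebo(example_tables):
    return ap.expand_frequency_table(example_tables["placebo"])


def random_rating_data(rng: np.random.Generator, k: int = 6) -> ap.RatingData:
    """Small random ordinal dataset with at least one item per class."""
    m = int(rng.integers(1, 30))
    n = int(rng.integers(1, 30))
    return ap.RatingData(
        labels=np.concatenate([np.ones(m, dtype=np.int8), np.zeros(n, dtype=np.int8)]),
        scores=rng.integers(1, k + 1, size=m + n).astype(float),
    )
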