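import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from icitau.matrix import AbundanceMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

NA = np.nan


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_matrix():
    """4 features x 4 samples with a sprinkling of missing values."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 4.0, 2.5, NA],
            "s2": [1.2, 4.1, 2.4, 8.0],
            "s3": [0.9, NA, 2.6, 7.5],
            "s4": [5.0, 1.0, 9.0, 0.5],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    return AbundanceMatrix.from_frame(data)


def random_missing_pair(rng, n_max=50, max_missing=0.6, ties=False):
    """Random vector pair with independent random missingness."""
    n = int(rng.integers(2, n_max + 1))
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    if ties and rng.random() < 0.5:
        x = np.round(x)
    if ties and rng.random() < 0.5:
        y = np.round(y, 1)
    x[rng.random(n) < rng.random() * max_missing] = np.nan
    y[rng.random(n) < rng.random() * max_missing] = np.nan
    return x, y
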