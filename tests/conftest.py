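import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from binimpute import DayMatrix, SynthConfig, generate_days

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hr30():
    """30 synthetic days at the generator defaults (seed 7)."""
    hr, _ = generate_days(SynthConfig(seed=7))
    return hr


def random_masked_matrix(rng, n=8, c=6, missing=0.2, offset=0):
    """A small random matrix with a given missing fraction (every column
    keeps at least one observed value so SI has donors)."""
    values = rng.uniform(50.0, 100.0, size=(n, c))
    mask = rng.random(size=(n, c)) < missing
    for j in range(c):
        if mask[:, j].all():
            mask[rng.integers(0, n), j] = False
    values[mask] = np.nan
    return DayMatrix([f"d{i}" for i in range(n)], values, offset)
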