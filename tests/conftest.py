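import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ciboost.data import SurvivalDataset, comparable_pairs

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_instance(rng, n, p=3, censor_frac=0.4, tie_frac=0.0):
    """A random censored cohort guaranteed to have comparable pairs."""
    while True:
        time = rng.exponential(1.0, n) + 1e-3
        if tie_frac > 0:  # force exact time ties
            k = max(2, int(tie_frac * n))
            time[:k] = time[0]
        status = (rng.random(n) > censor_frac).astype(int)
        data = SurvivalDataset(time, status, rng.standard_normal((n, p)))
        if comparable_pairs(data).size > 0:
            return data


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_all_events():
    """Three subjects, all events, one covariate; pairs (0,1),(0,2),(1,2)."""
    return SurvivalDataset([1.0, 2.0, 3.0], [1, 1, 1], [[0.0], [1.0], [2.0]])
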