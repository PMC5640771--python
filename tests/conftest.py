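import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tau_a_oracle(x, y):
    """Independent O(n^2) brute-force tau-a: explicit loop over item pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return s / (n * (n - 1) / 2)


def random_rdm(rng, n=8, metric="judged_distance", ids=None):
    from rsaweight import RDM

    ids = ids or tuple(f"c{i}" for i in range(n))
    vals = rng.random(n * (n - 1) // 2) + 0.05
    return RDM(ids, vals, metric)
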