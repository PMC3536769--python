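import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    """Equal-weight triangle graph."""
    from netperm import ConnectivityMatrix

    w = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    return ConnectivityMatrix(w, ("a", "b", "c"), kind="coherence")


@pytest.fixture
def path3():
    """3-node path a-b-c, binary."""
    from netperm import ConnectivityMatrix

    w = np.array([[0, 1.0, 0], [1.0, 0, 1.0], [0, 1.0, 0]])
    return ConnectivityMatrix(w, ("a", "b", "c"), kind="binary")
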