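import numpy as np
import pytest

from concertsync import AudienceSpec, Channel, generate_audience


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_coupled_audience():
    """m=5 audience, gain 0.6, zero lags: reused by several modules."""
    spec = AudienceSpec(
        m=5, duration_s=300.0, seed=11,
        gains=np.full(5, 0.6), lags_s=np.zeros(5),
        channels=(Channel.HR, Channel.MOVE),
    )
    channels, truth = generate_audience(spec)
    return channels, truth
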