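import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_track(rng, n_steps=50, species="human", cell_id="c0", dt=10.0):
    """Arbitrary valid track with uniform frame spacing."""
    from pannpc.migration import Track

    t = np.arange(n_steps + 1) * dt
    xy = np.cumsum(rng.normal(0, 5.0, (n_steps + 1, 2)), axis=0) + 300.0
    return Track(cell_id, species, np.column_stack([t, xy]))
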