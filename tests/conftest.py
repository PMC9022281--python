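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
    return np.random.default_rng(20220421)


@pytest.fixture
def small_panel():
    """A 300 x 12 diploid panel with moderate LD and its LD matrix."""
    from triangulate.simulate import simulate_panel

    return simulate_panel(300, 12, ld_decay=0.5, seed=4)
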