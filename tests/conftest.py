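import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcspcfit import ChannelGrid, DecayTrace

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def grid() -> ChannelGrid:
    """Default instrument grid: 1024 channels at 40 ps, time zero at ch 64."""
    return ChannelGrid(n_channels=1024, dwell=0.040, t0_channel=64)


@pytest.fixture
def delta_irf(grid) -> DecayTrace:
    """Single-channel (identity-kernel) IRF at the grid's time zero."""
    counts = np.zeros(grid.n_channels)
    counts[grid.t0_channel] = 1.0
    return DecayTrace(grid=grid, counts=counts, kind="irf")
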