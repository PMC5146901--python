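import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhythmoscope import StudyDesign

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def design():
    """The study's sampling layout: ZT0..24 step 3, n=6, fixed seed."""
    return StudyDesign(seed=0)


@pytest.fixture
def times9():
    """The nine design Zeitgeber times (ZT0 and ZT24 both sampled)."""
    return np.arange(0.0, 25.0, 3.0)


@pytest.fixture
def times54(times9):
    """Replicate-level time vector: 9 timepoints x 6 fish."""
    return np.repeat(times9, 6)
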