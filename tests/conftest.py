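import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "beamqa",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("beamqa")


@pytest.fixture
def depths_fine():
    """0-30 cm at 0.1 cm spacing, the standard water-tank depth grid."""
    return np.round(np.arange(0.0, 30.0 + 1e-9, 0.1), 10)


@pytest.fixture
def positions_mm():
    """Symmetric off-axis grid at 0.5 mm spacing, wide enough for a 10x10 field."""
    return np.linspace(-90.0, 90.0, 361)
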