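import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circadia import RhythmScanner, TimeGrid

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    """The study's sampling design: every 2 h for 48 h."""
    return TimeGrid.regular(0.0, 46.0, 2.0)


@pytest.fixture(scope="session")
def scanner(grid) -> RhythmScanner:
    """Default 10-40 h scanner on the 2-h grid, shared across tests."""
    return RhythmScanner(grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
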