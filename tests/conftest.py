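import numpy as np
import pytest

from sensemaker.memory import ActivationParams
from sensemaker.taskenv import RoadNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet():
    """Deterministic kernel parameters (noise off, default scales)."""
    return ActivationParams(noise_on=False)


@pytest.fixture
def cross_roads():
    """Two perpendicular straight roads crossing at (50, 50)."""
    return RoadNetwork([[(0.0, 50.0), (100.0, 50.0)], [(50.0, 0.0), (50.0, 100.0)]])


@pytest.fixture
def l_network():
    """An L-shaped road (corner at (50,50), ends (0,50) and (50,0)) plus a
    straight road crossing both arms."""
    return RoadNetwork(
        [[(0.0, 50.0), (50.0, 50.0), (50.0, 0.0)], [(0.0, 0.0), (100.0, 100.0)]]
    )
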