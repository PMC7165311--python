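import numpy as np
import pytest

from fallwarp import TriaxialAccelerationSignal, default_protocol, simulate_fall


@pytest.fixture(scope="session")
def simulated_fall():
    """A default six-phase simulated fall with its ground-truth annotations."""
    return simulate_fall(default_protocol(seed=123))


@pytest.fixture
def small_signal():
    """A tiny hand-built signal at 100 Hz (5 samples)."""
    data = np.array(
        [
            [0.0, 0.01, 1.0],
            [0.1, -0.02, 0.98],
            [0.2, 0.0, 1.05],
            [0.15, 0.03, 0.97],
            [0.05, -0.01, 1.01],
        ]
    )
    return TriaxialAccelerationSignal(data=data, sampling_rate_hz=100.0)
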