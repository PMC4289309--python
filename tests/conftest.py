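import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles as `oracles`

from sprimage import OpticalLayer, OpticalStack, gold_sensor_stack


@pytest.fixture(scope="session")
def gold_stack_620():
    """Glass(1.78)/45 nm gold/water sensor stack at 620 nm."""
    return gold_sensor_stack(620.0)


@pytest.fixture()
def glass_water_stack():
    """Lossless two-medium stack (critical angle ≈ 48.5°)."""
    return OpticalStack(
        [OpticalLayer("glass", 1.78**2), OpticalLayer("water", 1.333**2)], 620.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
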