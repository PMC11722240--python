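import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from notchdyn.circuit import CircuitParams, simulate_pair

#: Fig-style reference parameter points: low KD (healthy-like lateral
#: inhibition) and elevated KD (injury-like feedback loss).
POINT1 = CircuitParams(kn=0.5, kd=0.25)
POINT2 = CircuitParams(kn=0.5, kd=1.0)


@pytest.fixture(scope="session")
def traj_point1():
    return simulate_pair(POINT1)


@pytest.fixture(scope="session")
def traj_point2():
    return simulate_pair(POINT2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
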