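import math

import numpy as np
import pytest

from cellmech.afm import ProbeGeometry


@pytest.fixture
def sphere_probe() -> ProbeGeometry:
    """Colloidal sphere probe as used for tissue and whole-cell stiffness."""
    return ProbeGeometry(kind="sphere", R=2.5e-6, spring_constant=0.03)


@pytest.fixture
def cone_probe() -> ProbeGeometry:
    """Nanoneedle-style conical probe (half angle 3.9 deg)."""
    return ProbeGeometry(kind="cone", theta=math.radians(3.9), spring_constant=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
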