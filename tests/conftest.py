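import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes tests/oracles.py importable

from maskblock import EmissionModel, ExperimentGeometry, FluidEnvironment


@pytest.fixture
def env():
    return FluidEnvironment()


@pytest.fixture
def geometry():
    return ExperimentGeometry()


@pytest.fixture
def small_emission():
    """A reduced emitted population for fast simulator tests."""
    return EmissionModel(count=20_000, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
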