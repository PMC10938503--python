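import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from fiberbloom import (
    FiberGeometry,
    GeneratorConfig,
    TransportParameters,
)

# study conditions: D for ROY in polyethylene, 0.6 mm fiber diameter
D_REF = 3.5e-11  # cm^2/s
R_REF = 0.03     # cm


@pytest.fixture
def geometry() -> FiberGeometry:
    return FiberGeometry(radius_cm=R_REF)


@pytest.fixture
def transport() -> TransportParameters:
    return TransportParameters(diffusion_coeff_cm2_s=D_REF, initial_conc_frac=0.01)


@pytest.fixture
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=42)


@pytest.fixture
def day_times() -> np.ndarray:
    """Observation schedule (seconds) spanning the release transient."""
    return np.array([1, 2, 4, 8, 16, 32, 64, 125], dtype=float) * 86400.0
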