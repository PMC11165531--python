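import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tmmchar as tc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def water():
    return tc.WaterReference()


@pytest.fixture(scope="session")
def acoustic_geom():
    """Standard 6 mm solid specimen in the acoustic path."""
    return tc.SpecimenGeometry(mode="solid_acoustic", thickness_d=6e-3)


@pytest.fixture(scope="session")
def materials():
    """The five packaged measured-material records."""
    return tc.load_material_records()


@pytest.fixture(scope="session")
def compression():
    """10 mm indenter on a 6 mm cylindrical specimen, 2 mm plunge."""
    return tc.compression_protocol()


@pytest.fixture
def burst_cfg():
    return tc.SimulationConfig()


def forward_delay(c_medium: float, d: float, c_water: float = 1481.0) -> float:
    """Independent oracle: time offset the substitution relation predicts
    for a specimen of speed c_medium and thickness d (positive = earlier)."""
    return d * (1.0 / c_water - 1.0 / c_medium)
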