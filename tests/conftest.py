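import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from electrotonus import (
    CableGeometry,
    CableModelSpec,
    PassiveProperties,
    SolverConfig,
    run_electrotonus,
)

# passive values of the showcase models: Rm = 1e4 Ω·cm², Ra = 100 Ω·cm
REFERENCE_PASSIVE = PassiveProperties()

#: reduced-resolution profile for batch-style tests
COARSE = SolverConfig(dx=5.0, dt=0.1, settle_time=50.0, record_dt=0.5)


@pytest.fixture(scope="session")
def classic_spec():
    """Uniform 0.5 µm cable — the classic thin-cable model."""
    return CableModelSpec(CableGeometry.uniform(0.5), REFERENCE_PASSIVE)


@pytest.fixture(scope="session")
def tapered_spec():
    """20 → 0.5 µm linear taper — the wide tapered neurite model."""
    return CableModelSpec(CableGeometry(d0=20.0, d1=0.5), REFERENCE_PASSIVE)


@pytest.fixture(scope="session")
def classic_electrotonus(classic_spec):
    return run_electrotonus(classic_spec)


@pytest.fixture(scope="session")
def tapered_electrotonus(tapered_spec):
    return run_electrotonus(tapered_spec)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results don't depend on order
    return np.random.default_rng(20260928)
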