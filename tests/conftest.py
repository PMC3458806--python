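import numpy as np
import pytest

from frapmc.frap_sim import (
    AcquisitionProtocol,
    BleachProfile,
    MobilityParams,
    NucleusGeometry,
)


@pytest.fixture(scope="session")
def geometry() -> NucleusGeometry:
    return NucleusGeometry()


@pytest.fixture(scope="session")
def profile() -> BleachProfile:
    return BleachProfile()


@pytest.fixture(scope="session")
def tel_params() -> MobilityParams:
    """Published TEL-GFP best fit: 57% bound 0.63 s, 20% bound 59 s."""
    return MobilityParams(D=3.0, f1=0.57, T1=0.63, f2=0.20, T2=59.0)


@pytest.fixture(scope="session")
def short_protocol() -> AcquisitionProtocol:
    """Abbreviated schedule for unit tests: 150 scans, bleach after 30."""
    return AcquisitionProtocol(
        n_scans=150, n_prebleach=30, sim_substep=0.007
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
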