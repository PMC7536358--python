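import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcdsim.noise import NoiseSources, reference_calibration
from pcdsim.readout import ShaperConfig
from pcdsim.transport import DetectorGeometry, solve_field, standard_pulse_ensemble

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def fieldmap(geometry):
    return solve_field(geometry)


@pytest.fixture(scope="session")
def ideal_config():
    """Future-channel reference configuration: tau = 40 ns."""
    return ShaperConfig.ideal(20.0)


@pytest.fixture(scope="session")
def sources():
    return NoiseSources()


@pytest.fixture(scope="session")
def calibration(sources):
    return reference_calibration(sources)


@pytest.fixture(scope="session")
def gain_ensemble(geometry):
    """Shared seeded pulse ensembles at the beam energies of the campaign."""
    return standard_pulse_ensemble([40.0, 60.0, 70.0, 80.0], geometry=geometry,
                                   n_pulses=20, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
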