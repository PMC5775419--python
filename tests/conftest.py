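import numpy as np
import pytest

from sweatwatch.actuator import ExpansionFluid, PF5060, circuit_from_geometry
from sweatwatch.synth import CycleTiming, SensorTruth


@pytest.fixture
def default_timing():
    return CycleTiming()


@pytest.fixture
def noiseless_truth():
    return SensorTruth(noise_sd=0.0)


@pytest.fixture
def default_circuit():
    """The documented watch-type device at its 0.4 ml design point."""
    return circuit_from_geometry()


@pytest.fixture
def volatile_fluid():
    """A fluid with full vapor-pressure constants for Clausius-Clapeyron tests."""
    return ExpansionFluid(
        name="test-fluid",
        boiling_temp_c=56.0,
        density=1.68,
        specific_heat=1.05,
        pressure_at_boiling=101325.0,
        vaporization_enthalpy=30000.0,
    )


def random_circuit(rng: np.random.Generator):
    """A random physically valid thermal circuit."""
    return circuit_from_geometry(
        heater_voltage=rng.uniform(3, 12),
        heater_resistance=rng.uniform(5, 100),
        fluid_volume_ml=rng.uniform(0.05, 2.0),
        air_h=rng.uniform(5, 50),
        wall_k=rng.uniform(0.1, 1.0),
        wall_thickness=rng.uniform(0.002, 0.02),
        membrane_area=rng.uniform(1e-4, 2e-3),
        ambient_temp_c=rng.uniform(10, 35),
    )
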