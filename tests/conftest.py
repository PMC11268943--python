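import numpy as np
import pytest

from oxycpap import allocation as alloc
from oxycpap import concentrator as conc
from oxycpap.plant import PlantConfig
from oxycpap.protocol import ProtocolGrid, run_validation_grid


@pytest.fixture(scope="session")
def surfaces():
    return conc.TruthSurfaces()


@pytest.fixture(scope="session")
def char_table(surfaces):
    return conc.run_characterization(surfaces)


@pytest.fixture(scope="session")
def coeffs(char_table):
    return conc.fit_inverse_cs(char_table), conc.fit_inverse_sv(char_table)


@pytest.fixture(scope="session")
def lookup(coeffs):
    return alloc.build_lookup_table(*coeffs)


@pytest.fixture(scope="session")
def fast_grid_records(surfaces):
    """Full 120-point validation grid, CI profile (dt=5 ms), noise on."""
    grid = ProtocolGrid().fast()
    plant = PlantConfig(dt=0.005)
    return run_validation_grid(grid, plant_config=plant, surfaces=surfaces)


@pytest.fixture(scope="session")
def noiseless_plant():
    return PlantConfig(o2_sensor_noise_sd=0.0)
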