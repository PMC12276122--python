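import numpy as np
import pytest

from microsolv.conformer_io import ConformerRecord
from microsolv.rrho import TemperatureGrid
from microsolv.synthetic import (ScenarioSpec, generate_hydration_scenario,
                                 water_geometry)


@pytest.fixture
def argon_record():
    return ConformerRecord(
        label="Ar", species="PBA", n_waters=0, phase="gas",
        elements=["Ar"], coordinates=[[0.0, 0.0, 0.0]],
        electronic_energy=0.0, frequencies=[], mass=39.948,
    )


@pytest.fixture
def water_record():
    el, xyz = water_geometry()
    return ConformerRecord(
        label="W1", species="WATER_CLUSTER", n_waters=1, phase="gas",
        elements=el, coordinates=xyz, electronic_energy=-76.43,
        frequencies=[1649.0, 3695.2, 3801.6],
    )


@pytest.fixture
def default_grid():
    return TemperatureGrid()


@pytest.fixture
def small_spec():
    return ScenarioSpec(seed=7, sizes=(1, 2, 3, 5, 6), isomers_per_size=4)


@pytest.fixture(scope="session")
def default_scenario():
    """The bundled synthetic hydration scenario at its default conditions."""
    return generate_hydration_scenario(ScenarioSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
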