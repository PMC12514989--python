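import numpy as np
import pytest

from conespot import spectral_model as sm
from conespot import synthetic_data as sd
from conespot.stimulation_optics import StimulationKernel, StimulusSpec


@pytest.fixture(scope="session")
def mosaic():
    """Default study-like mosaic: ~6400 cones, L/(L+M) ~ 0.595."""
    return sd.generate_mosaic(sd.MosaicSpec(seed=42))


@pytest.fixture(scope="session")
def l_rich_mosaic():
    """Mosaic emulating the L-rich subject (L/M ratio 3.66)."""
    return sd.generate_mosaic(
        sd.MosaicSpec(global_prop_L=sd.PROP_L_SUBJECT_B, seed=43))


@pytest.fixture(scope="session")
def kernel543():
    return StimulationKernel(StimulusSpec(wavelength=543.0))


@pytest.fixture(scope="session")
def kernel680():
    return StimulationKernel(StimulusSpec(wavelength=680.0))


@pytest.fixture(scope="session")
def observer():
    return sd.ObserverSpec()


@pytest.fixture(scope="session")
def fundamentals(observer):
    return sd.observer_fundamentals(observer)


@pytest.fixture(scope="session")
def excitation_table():
    """L-cone lambda_max -> excitation dict, 550-570 nm at 0.1 nm."""
    grid = np.round(np.arange(550.0, 570.01, 0.1), 1)
    filters = sm.PreReceptoralFilters.from_age(40.0, 2.0)
    table = {}
    for lm in grid:
        pig = sm.PigmentSpec(
            lambda_max={"L": float(lm), "M": 530.0, "S": 420.0},
            outer_segment_length=35.7)
        table[float(lm)] = sm.build_fundamentals(filters, pig).excitations()
    return grid, table
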