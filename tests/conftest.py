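import numpy as np
import pytest

from hpcmri.phantoms import HistoPhantomSpec, generate_dab_phantom, generate_he_phantom
from hpcmri.simulate import ExchangeParams, make_vfa_schedule, simulate_hp_dynamics


@pytest.fixture(scope="session")
def default_schedule():
    return make_vfa_schedule()


@pytest.fixture(scope="session")
def default_series(default_schedule):
    """Noiseless dynamic series under the default kinetics (kPL = 0.02 s⁻¹)."""
    return simulate_hp_dynamics(ExchangeParams(), default_schedule)


@pytest.fixture(scope="session")
def he_phantom_16pct():
    """1024² H&E phantom at 16% nuclear area (low-cellularity tumor regime)."""
    return generate_he_phantom(
        HistoPhantomSpec(image_shape=(1024, 1024), target_nuclei_fraction=0.16, seed=11)
    )


@pytest.fixture(scope="session")
def dab_phantom_10pct():
    """1024² DAB phantom at 9.87% stained tissue (high-MCT4 tumor regime)."""
    return generate_dab_phantom(
        HistoPhantomSpec(image_shape=(1024, 1024), target_stain_fraction=0.0987, seed=12)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
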