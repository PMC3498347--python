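import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from rumblecam.array_model import ImagePlane, PropagationModel, build_star_array
from rumblecam.synthetic_data import (
    add_noise,
    sample_call_population,
    synthesize_call,
)


@pytest.fixture(scope="session")
def star48():
    return build_star_array()


@pytest.fixture(scope="session")
def propagation():
    return PropagationModel()


@pytest.fixture(scope="session")
def small_plane():
    # coarse grid keeps map tests fast; pixel ~ 10 cm
    return ImagePlane(distance=8.0, width=4.0, height=3.0, nx=40, ny=30)


@pytest.fixture(scope="session")
def small_corpus():
    """20 nasal + 20 oral calls at SNR 20 dB with their specs."""
    specs = sample_call_population(20, 20, seed=101)
    calls = [
        add_noise(synthesize_call(s), snr_db=20.0, seed=s.seed + 1) for s in specs
    ]
    return specs, calls
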