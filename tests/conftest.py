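import numpy as np
import pytest

from microq import IonBeamSpec, frequency_to_dose, triangular_spectrum
from microq.synthetic import study_beams


@pytest.fixture(scope="session")
def beams():
    """The six study ion beams, H through Fe."""
    return study_beams()


@pytest.fixture(scope="session")
def dose_spectra(beams):
    """Triangular dose-weighted spectra for the six study LETs."""
    return tuple(frequency_to_dose(triangular_spectrum(b)) for b in beams)


@pytest.fixture
def carbon_beam():
    return IonBeamSpec("C", 13.0, 290.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20220127)
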