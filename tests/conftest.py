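import numpy as np
import pandas as pd
import pytest

from ripescan import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def mandarin_cohort():
    """Default 68-sample mandarin cohort (seed 1): traits, spectra, rgb."""
    return simulate_cohort(SimConfig("mandarin", seed=1))


@pytest.fixture(scope="session")
def tomato_cohort():
    """Default 68-sample tomato cohort (seed 1)."""
    return simulate_cohort(SimConfig("tomato", seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240826)


@pytest.fixture()
def flat_spectrum():
    from ripescan import Spectrum
    from ripescan.simulate import WAVELENGTH_GRID

    return Spectrum(WAVELENGTH_GRID.copy(), np.full(WAVELENGTH_GRID.size, 0.5))
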