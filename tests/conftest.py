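import numpy as np
import pytest

from uavtraits import lut_sampling, synthetic_data
from uavtraits.trait_core import SensorModel


def band_columns(df):
    return [c for c in df.columns
            if c.startswith("b") and not c.startswith("true_")]


@pytest.fixture(scope="session")
def sensor():
    return SensorModel.gamaya_oxi()


@pytest.fixture(scope="session")
def small_lut_reg():
    """Correlated LUT at reduced size for fast tests."""
    return lut_sampling.build_lut("reg", n=2000, rng=11)


@pytest.fixture(scope="session")
def small_lut_std():
    return lut_sampling.build_lut("std", n=2000, rng=11)


@pytest.fixture(scope="session")
def noise_free_lut():
    return lut_sampling.build_lut("reg", n=800, noise_sigma=0.0, rng=7)


@pytest.fixture(scope="session")
def campaign():
    """Default synthetic campaign with observed spectra."""
    plots = synthetic_data.generate_campaign(rng=21)
    return synthetic_data.generate_spectra(plots, rng=22)
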