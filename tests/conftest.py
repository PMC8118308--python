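import numpy as np
import pytest

from crystalscope.io import WavenumberAxis
from crystalscope.spectra import ReferenceLibrary
from crystalscope.synth import CH_STRETCH_AXIS, FINGERPRINT_AXIS


@pytest.fixture(scope="session")
def ch_axis() -> WavenumberAxis:
    return CH_STRETCH_AXIS


@pytest.fixture(scope="session")
def fp_axis() -> WavenumberAxis:
    return FINGERPRINT_AXIS


@pytest.fixture(scope="session")
def ch_library(ch_axis) -> ReferenceLibrary:
    return ReferenceLibrary.from_band_model(ch_axis)


@pytest.fixture(scope="session")
def fp_library(fp_axis) -> ReferenceLibrary:
    return ReferenceLibrary.from_band_model(fp_axis)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
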