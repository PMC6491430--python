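import numpy as np
import pytest

from daisysmlm import CalibrationBundle, OpticalModel


@pytest.fixture(scope="session")
def optics() -> OpticalModel:
    return OpticalModel()


@pytest.fixture(scope="session")
def bundle(optics) -> CalibrationBundle:
    return CalibrationBundle.from_optics(optics)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
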