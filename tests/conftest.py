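import numpy as np
import pytest

from olfbold.paradigm import analysis_windows, build_paradigm
from olfbold.synthetic import make_atlas


@pytest.fixture(scope="session")
def paradigm():
    """The default olfactory design: 60 s baseline + 3 x (60 s on / 120 s off), TR 2 s."""
    return build_paradigm(2.0, 60.0, 3, 60.0, 120.0)


@pytest.fixture(scope="session")
def windows(paradigm):
    return analysis_windows(paradigm)


@pytest.fixture(scope="session")
def atlas():
    return make_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
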