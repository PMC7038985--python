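import numpy as np
import pytest

from dnastretch import FrameAnalyzer, build_duplex


@pytest.fixture(scope="session")
def at24():
    return build_duplex("AT" * 12)


@pytest.fixture(scope="session")
def cg24():
    return build_duplex("CG" * 12)


@pytest.fixture(scope="session")
def at24_analyzer(at24):
    return FrameAnalyzer(at24)


@pytest.fixture(scope="session")
def cg24_analyzer(cg24):
    return FrameAnalyzer(cg24)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
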