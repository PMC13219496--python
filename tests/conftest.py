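import pytest

from cici_cal.presets import demo_bins, demo_model, demo_pairs


@pytest.fixture(scope="session")
def model():
    return demo_model()


@pytest.fixture(scope="session")
def bins():
    return demo_bins(seed=7)


@pytest.fixture(scope="session")
def pairs():
    return demo_pairs()


@pytest.fixture(scope="session")
def intra_pair(pairs):
    return pairs["pair1"]


@pytest.fixture(scope="session")
def inter_pair(pairs):
    return pairs["pair2"]
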