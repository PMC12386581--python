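import pytest

from bppfit import SpectrometerConfig, load_reference_model


@pytest.fixture(scope="session")
def config():
    return SpectrometerConfig()


@pytest.fixture(scope="session")
def mag0():
    return load_reference_model("mag_0kGy")


@pytest.fixture(scope="session")
def hon0():
    return load_reference_model("hon_0kGy")
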