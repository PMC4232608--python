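import pytest

from circlekeeper import get_preset


@pytest.fixture
def wt():
    return get_preset("wt")


@pytest.fixture
def noiseless_image_preset():
    """wt-loaded imaging preset with shot and read noise disabled."""
    return get_preset("wt-loaded").replace(gain=0.0, read_noise_sd=0.0)


@pytest.fixture
def noiseless_rim_preset():
    return get_preset("rim-wt").replace(noise_sd=0.0, red_noise_sd=0.0)


@pytest.fixture
def noiseless_flip_preset():
    return get_preset("flip-wt-circle").replace(noise_sd=0.0)
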