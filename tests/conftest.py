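import numpy as np
import pytest

from sishscore import score_image
from sishscore.io import load_table4_fixture
from sishscore.synthetic import generate_roi, preset


@pytest.fixture(scope="session")
def table4():
    return load_table4_fixture()


@pytest.fixture(scope="session")
def amplified_scene():
    """Noise-free amplified scene (30 nuclei, 6 HER2 / 2 CEP17 each) plus
    the pipeline outputs on it."""
    roi, truth = generate_roi(preset("amplified", seed=11), "amplified_test")
    result, inter = score_image(roi, return_intermediates=True)
    return roi, truth, result, inter


@pytest.fixture(scope="session")
def normal_scene():
    roi, truth = generate_roi(preset("normal", seed=11), "normal_test")
    result, inter = score_image(roi, return_intermediates=True)
    return roi, truth, result, inter


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
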