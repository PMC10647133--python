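import numpy as np
import pytest

from phytochroma import correction, synthetic


@pytest.fixture(scope="session")
def reference():
    return correction.default_reference_swatches()


@pytest.fixture(scope="session")
def clean_scene():
    """Rendered default capture: checker, reference square, three discs."""
    return synthetic.render_scene(synthetic.default_scene(seed=0))


@pytest.fixture(scope="session")
def distorted_scene(clean_scene):
    """The default capture under moderate cast + vignette 0.2 + noise SD 2."""
    img, truth = clean_scene
    distorted = synthetic.apply_camera_distortion(
        img, cast=synthetic.DEFAULT_CAST, vignette_strength=0.2, noise_sd=2.0, seed=1
    )
    return distorted, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
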