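import numpy as np
import pytest

from volehabitat.scene import SceneParams


@pytest.fixture
def small_params() -> SceneParams:
    """A 20 m x 16 m quadrat (80 tiles) that renders in well under a second."""
    return SceneParams(
        quadrat_width=20.0,
        quadrat_height=16.0,
        flower_parent_intensity=0.05,
        flower_mean_offspring=60.0,
        noise_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
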