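import numpy as np
import pytest

from v1sal import SaliencyModel
from v1sal.stimuli import oriented_texture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


# One trained model shared by the slower integration/acceptance tests.
# Training geometry mirrors the package defaults for the search-array
# experiments: 49 filters (7x7 torus) of 16x16 pixels learned from the
# built-in oriented-texture corpus.
TRAIN_KW = dict(
    seed=1,
    patch_side=16,
    n_train_images=40,
    n_patches=20_000,
    n_iterations=3000,
    step_size=1.0,
)


@pytest.fixture(scope="session")
def trained_model():
    model = SaliencyModel(**TRAIN_KW)
    model.fit(None)
    return model


@pytest.fixture(scope="session")
def texture_images():
    return [oriented_texture(seed=500 + k) for k in range(8)]
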