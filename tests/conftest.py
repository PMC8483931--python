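import numpy as np
import pytest

import redct
from redct.synthetic_ct import Ellipse, PhantomSpec


@pytest.fixture(scope="session")
def water_disc() -> redct.CTImage:
    """32x32 phantom: a centered water disc in air."""
    spec = PhantomSpec(32, (Ellipse((0.5, 0.5), (0.4, 0.4), 0.0, "water"),))
    return redct.generate_phantom(spec)


@pytest.fixture(scope="session")
def body_phantom() -> redct.CTImage:
    """64x64 torso-like phantom with water body, soft and bone inserts."""
    return redct.generate_phantom(redct.random_phantom_spec(3, canvas_size=64))


@pytest.fixture(scope="session")
def trimodal_image() -> redct.CTImage:
    """Random mix of exactly -1000 / 0 / 1000 HU pixels."""
    rng = np.random.default_rng(11)
    values = np.choose(rng.integers(0, 3, size=(64, 64)),
                       [-1000.0, 0.0, 1000.0])
    return redct.CTImage(values)


@pytest.fixture(scope="session")
def small_model() -> redct.RecursiveREDModel:
    """Narrow seeded model (8 layers, 6 kernels) for fast forward passes."""
    cfg = redct.REDConfig(kernels_per_hidden_layer=6)
    return redct.build_model(cfg, seed=5, S=3)


@pytest.fixture(scope="session")
def extractor() -> redct.FeatureExtractor:
    return redct.FeatureExtractor.seeded(7)
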