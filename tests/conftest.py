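import numpy as np
import pytest

from propseg.config import ModelConfig
from propseg.phantom import PhantomParams


def tiny_config(**overrides) -> ModelConfig:
    """Smallest architecture that exercises every structural path."""
    base = dict(image_size=32, depth=2, channels=(3, 4), kernels=(3, 3), seed=0)
    base.update(overrides)
    return ModelConfig(**base).validate()


def tiny_phantom(**overrides) -> PhantomParams:
    """32x32 phantoms matching tiny_config geometry."""
    base = dict(n_slices=4, image_size=32, outer_radius=(5.0, 8.0),
                inner_radius=(2.5, 4.0), center_drift=1.0, radius_drift=0.5,
                seed=0)
    base.update(overrides)
    return PhantomParams(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
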