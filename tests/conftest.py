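import numpy as np
import pytest

from wmhkit import PhantomSpec, generate_phantom
from wmhkit.config import PipelineConfig
from wmhkit.pipeline import segment_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=(48, 48, 48), target_lesion_ml=3.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def segmented(small_phantom):
    """The automated segmenter run once on the small phantom."""
    cfg = PipelineConfig(grid_shape=(48, 48, 48), target_lesion_ml=3.0, seed=7)
    return segment_phantom(small_phantom, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
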