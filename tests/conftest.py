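import numpy as np
import pytest

from cosiquant import PipelineConfig, SimulationSpec


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_spec():
    """A modest field: 12 well-separated bright spots on Poisson background."""
    return SimulationSpec(n_spots=12, image_shape_px=(192, 192), seed=11)
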