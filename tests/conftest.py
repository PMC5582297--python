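import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture()
def small_volume():
    """A tiny hand-countable labeled volume: 10x10x10 with 100 nucleus and
    200 extracellular voxels, 70 myofibril, 30 mitochondria."""
    from oftquant.volumetrics import CLASS_CODES, LabeledVolume

    grid = np.zeros((10, 10, 10), dtype=np.uint8)
    grid.ravel()[:100] = CLASS_CODES["nucleus"]
    grid.ravel()[100:300] = CLASS_CODES["extracellular"]
    grid.ravel()[300:370] = CLASS_CODES["myofibril"]
    grid.ravel()[370:400] = CLASS_CODES["mitochondria"]
    return LabeledVolume(class_grid=grid, voxel_size=(20.0, 20.0, 4.0))
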