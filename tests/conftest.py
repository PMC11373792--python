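import numpy as np
import pytest

from hyperseed.hsi_io import HyperCube, default_calibration
from hyperseed.synthetic import default_three_class_spec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 3-class scene at reduced band count for speed."""
    from dataclasses import replace

    spec = default_three_class_spec(rng_seed=7, band_count=462)
    spec = replace(spec, image_size=(120, 160), seeds_per_class=3)
    return generate_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cube():
    rng = np.random.default_rng(0)
    data = rng.random((5, 7, 11)).astype(np.float32)
    return HyperCube(data=data, interleave="bil", calibration=default_calibration(11))
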