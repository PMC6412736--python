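import numpy as np
import pytest

from hsibrain import synthetic
from hsibrain.hsio import RawCube, ReferencePair
from hsibrain.preprocess import preprocess_chain


@pytest.fixture(scope="session")
def small_scene():
    """One quantized default-noise 64x64 scene."""
    return synthetic.generate_scene(synthetic.SceneConfig(seed=42))


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise, flat-illumination, unquantized scene (exact calibration)."""
    cfg = synthetic.SceneConfig(
        seed=42, noise_sd=0.0, illumination_gradient=0.0, quantize_bits=None
    )
    return synthetic.generate_scene(cfg)


@pytest.fixture(scope="session")
def processed_cube(small_scene):
    return preprocess_chain(small_scene.cube, small_scene.refs)


@pytest.fixture
def tiny_cube():
    """A 2x2x3 cube with hand-set values for I/O round-trips."""
    data = np.arange(12, dtype=np.float32).reshape(2, 2, 3) + 0.5
    return RawCube(data, np.array([400.0, 500.0, 600.0]))


def make_refs(shape, white=200.0, dark=50.0):
    return ReferencePair(np.full(shape, white), np.full(shape, dark))
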