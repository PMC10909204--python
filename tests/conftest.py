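import numpy as np
import pytest

from proj2proj.geometry import ProjectionGeometry, RadonTransform


@pytest.fixture(scope="session")
def small_geom() -> ProjectionGeometry:
    """32x32 image, 24 views — big enough to be nondegenerate, fast to build."""
    return ProjectionGeometry(image_size=32, n_views=24, n_detectors=32)


@pytest.fixture(scope="session")
def small_projector(small_geom) -> RadonTransform:
    return RadonTransform(small_geom)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
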