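import numpy as np
import pytest

from ibsa import SegmentationConfig, sphere_phantom


@pytest.fixture(scope="session")
def small_cfg():
    """Segmentation config with a volume floor suited to bench-top phantoms."""
    return SegmentationConfig(min_component_volume_ml=10.0)


@pytest.fixture(scope="session")
def sphere50():
    """Solid sphere, r = 50 mm, 1 mm isotropic spacing, noise-free."""
    return sphere_phantom(50.0, 1.0)


@pytest.fixture(scope="session")
def sphere50_mask(sphere50, small_cfg):
    from ibsa import segment_body

    return segment_body(sphere50.ct, small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
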