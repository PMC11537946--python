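import numpy as np
import pytest

from octaquant import VascularNetworkSpec, generate_network

# deliberately sparse/small network used where tests need many images fast
LIGHT = dict(image_size=128, n_seeds=4, branch_prob=0.02, caliber_root_px=2.0)


@pytest.fixture(scope="session")
def light_network():
    """Factory: (ProjectionMap, GeometryRecord) for a small seeded network."""

    def _make(seed: int, **overrides):
        kw = {**LIGHT, **overrides, "rng_seed": seed}
        return generate_network(VascularNetworkSpec(**kw))

    return _make


@pytest.fixture(scope="session")
def default_map():
    """One full-size (256 px) seeded map with its geometry record."""
    return generate_network(VascularNetworkSpec(rng_seed=42))


def rect_mask(shape=(256, 256), r0=100, c0=50, height=5, width=100):
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + height, c0 : c0 + width] = True
    return m


def disc_mask(shape=(256, 256), center=(128, 128), radius=50):
    from skimage.draw import disk

    m = np.zeros(shape, dtype=bool)
    rr, cc = disk(center, radius)
    m[rr, cc] = True
    return m


def quarter_arc_mask(radius=80, width=1.5, shape=(256, 256), center=(200.0, 40.0)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rad = np.hypot(yy - center[0], xx - center[1])
    return (np.abs(rad - radius) <= width) & (yy <= center[0]) & (xx >= center[1])
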