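import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_star_polygon(rng, n_vertices=None):
    """Simple (star-shaped) random polygon around the origin."""
    k = int(n_vertices or rng.integers(6, 15))
    ang = np.sort(rng.uniform(0, 2 * np.pi, k))
    rad = rng.uniform(1.0, 3.0, k)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])


def disk_pixels(radius, center=(0, 0)):
    """Pixel set of a filled disk (rows, cols)."""
    r0, c0 = center
    n = int(np.ceil(radius)) + 2
    rr, cc = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1), indexing="ij")
    inside = rr**2 + cc**2 <= radius**2
    return np.column_stack([rr[inside] + r0, cc[inside] + c0])
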