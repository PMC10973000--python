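import numpy as np
import pytest

from dccabci.riemann import expm, sqrtm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, n=4, scale=1.0):
    """Well-conditioned random SPD matrix."""
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))


def spd_around(rng, prototype, dispersion=0.1):
    """Sample an SPD matrix near a prototype via a tangent-space Gaussian."""
    n = prototype.shape[0]
    g = rng.standard_normal((n, n))
    sym = dispersion * 0.5 * (g + g.T)
    h = sqrtm(prototype)
    return h @ expm(sym) @ h


@pytest.fixture
def random_spd_factory(rng):
    return lambda n=4, scale=1.0: random_spd(rng, n, scale)
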