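import numpy as np
import pytest

from usb1mech import surfaces


@pytest.fixture
def double_well():
    return surfaces.make_double_well(5.0, 2.0)


@pytest.fixture
def mechanism_surface():
    return surfaces.make_mechanism_surface(6.0, 21.6, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20241201)


def fd_gradient(fn, s, h=1e-5):
    """Central finite-difference gradient of a scalar field at point s."""
    s = np.asarray(s, dtype=float)
    g = np.zeros_like(s)
    for k in range(s.size):
        sp, sm = s.copy(), s.copy()
        sp[k] += h
        sm[k] -= h
        g[k] = (fn(sp) - fn(sm)) / (2 * h)
    return g
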