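import numpy as np
import pytest

from activesheet.softdisk import SoftDiskConfig, generate_packing


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_packing():
    """Relaxed 64-disk packing reused by several test modules."""
    return generate_packing(64, packing_fraction=1.0, polydispersity=0.3, seed=3)


@pytest.fixture
def two_disk():
    """Two unit disks with overlap 0.1 in a large box (k = 1)."""
    return SoftDiskConfig(
        positions=np.array([[4.0, 5.0], [5.9, 5.0]]),
        radii=np.array([1.0, 1.0]),
        box=np.array([10.0, 10.0]),
    )


def finite_difference_forces(energy_fn, positions, h=1e-6):
    """Central finite differences of a scalar energy over particle coordinates."""
    grad = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for a in range(2):
            p = positions.copy()
            p[i, a] += h
            ep = energy_fn(p)
            p[i, a] -= 2 * h
            em = energy_fn(p)
            grad[i, a] = (ep - em) / (2 * h)
    return -grad
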