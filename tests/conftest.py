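import numpy as np
import pytest

from nearbalance import ClrVector, basis_from_partition


COFFEE_LABELS = ("espresso", "milk", "syrup")

# worked 8-taxon CLR shift used throughout (sums to zero exactly)
WORKED_SHIFT = np.array([-0.1, -0.8, -0.1, -0.3, 0.1, 0.9, -0.6, 0.9])
WORKED_LABELS = tuple(f"t{i}" for i in range(1, 9))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def coffee_basis():
    """milk vs {espresso, syrup}, then espresso vs syrup."""
    return basis_from_partition(
        [({"milk"}, {"espresso", "syrup"}), ({"espresso"}, {"syrup"})],
        COFFEE_LABELS,
    )


@pytest.fixture
def worked_shift():
    return ClrVector(WORKED_SHIFT, WORKED_LABELS)


def random_clr(rng, d, labels=None):
    v = rng.standard_normal(d)
    v -= v.mean()
    return ClrVector(v, labels or tuple(f"t{i}" for i in range(1, d + 1)))
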