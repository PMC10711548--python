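import numpy as np
import pytest

from regionvelo import demux as dx
from regionvelo import synthkit as sk


@pytest.fixture(scope="session")
def small_pools():
    """Three pools of 8 barcodes, 9 bp, vendor-like separation."""
    return dx.build_barcode_pools(n=8, length=9, seed=42)


@pytest.fixture(scope="session")
def small_reference(small_pools):
    return dx.compose_reference(small_pools)


@pytest.fixture(scope="session")
def small_whitelist(small_pools):
    return [tuple(p.barcodes[k] for p in small_pools) for k in range(8)]


@pytest.fixture(scope="session")
def full_pools():
    """The 96-barcode x 3 pool design used by the larger demux checks."""
    return dx.build_barcode_pools(seed=5)


@pytest.fixture(scope="session")
def noiseless_population():
    return sk.generate_population(400, 12, noise="none", seed=7)


@pytest.fixture(scope="session")
def poisson_population():
    return sk.generate_population(600, 30, noise="poisson", seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
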