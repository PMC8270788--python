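import numpy as np
import pytest

from hicarch.matrix_core import BinTable, ContactMatrix
from hicarch import synthetic_data as sd


@pytest.fixture
def bins100():
    return BinTable("chrT", 100 * 10_000, 10_000)


@pytest.fixture
def bins20():
    return BinTable("chrT", 20 * 10_000, 10_000)


def make_matrix(dense, bin_size=10_000, chrom="chrT"):
    dense = np.asarray(dense, dtype=float)
    bins = BinTable(chrom, dense.shape[0] * bin_size, bin_size)
    return ContactMatrix.from_dense(bins, dense)


def random_symmetric(n, rng, scale=10.0):
    a = rng.random((n, n)) * scale
    return (a + a.T) / 2.0


@pytest.fixture(scope="session")
def default_sim():
    """One asymmetric default-fixture simulation shared across tests."""
    spec = sd.default_fixture(seed=0, asymmetric=True)
    matrix, truth = sd.simulate_contact_matrix(spec)
    return spec, matrix, truth
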