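import numpy as np
import pytest

from fpetconn import AcquisitionSpec, NetworkSpec, block_parcellation


@pytest.fixture(scope="session")
def small_acq():
    """Desk-scale acquisition: full study timing on a 20-voxel grid."""
    return AcquisitionSpec(grid_shape=(20, 20, 20))


@pytest.fixture(scope="session")
def small_net():
    return NetworkSpec(seed=123)


@pytest.fixture(scope="session")
def small_parc(small_acq, small_net):
    return block_parcellation(small_acq.grid_shape, small_net.n_roi,
                              small_acq.voxel_size_mm)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
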