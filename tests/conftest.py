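import warnings

import numpy as np
import pytest

from holoquant import phantom as ph

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_static():
    """Small noiseless single-frame phantom: cell + nucleus + 4 LDs."""
    spec = ph.static_spec(
        n_ld=4, n_mitochondria=0, seed=3, noise_sd=0.0,
        grid_shape=(16, 96, 96),
        cell=ph.CellGeometry(semi_axes_um=(2.5, 7.0, 7.0),
                             nucleus_semi_axes_um=(1.6, 3.0, 3.0)),
    )
    vol, gt = ph.make_cell_phantom(spec, 0)
    return spec, vol, gt


@pytest.fixture(scope="session")
def tiny_static_noisy():
    spec = ph.static_spec(
        n_ld=4, n_mitochondria=0, seed=3,
        grid_shape=(16, 96, 96),
        cell=ph.CellGeometry(semi_axes_um=(2.5, 7.0, 7.0),
                             nucleus_semi_axes_um=(1.6, 3.0, 3.0)),
    )
    vol, gt = ph.make_cell_phantom(spec, 0)
    return spec, vol, gt
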