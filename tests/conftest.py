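import numpy as np
import pytest

from murodyn.containers import CellGeometry, TwoStateParams


@pytest.fixture
def near_wt_params() -> TwoStateParams:
    """Two-state parameters around the wild-type operating point: 20%
    bound, free diffusion 0.075 um^2/s, 35 nm localization error, 60 ms
    frame interval."""
    return TwoStateParams(f_bound=0.2, d_free=0.075, d_bound=0.0, sigma_loc=0.035, dt=0.06)


@pytest.fixture
def rod_geometry() -> CellGeometry:
    return CellGeometry(length=3.0, diameter=0.9)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
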