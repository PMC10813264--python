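import numpy as np
import pytest

import biomotion as bm


@pytest.fixture(scope="session")
def model() -> bm.experiment.Model:
    """One fitted, calibrated default observer model for the whole session
    (training and calibration take ~half a minute)."""
    return bm.build_default_model()


@pytest.fixture(scope="session")
def grid() -> bm.GridSpec:
    return bm.build_grid()


@pytest.fixture(scope="session")
def layout():
    return bm.build_layout()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240103)
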