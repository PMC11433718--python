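import numpy as np
import pytest

from nanodoe import datasets


@pytest.fixture(scope="session")
def bbd_runs():
    """Packaged 17-run Box-Behnken table (design, responses, published OD)."""
    return datasets.load_bbd_runs()


@pytest.fixture(scope="session")
def bbd_design():
    return datasets.load_bbd_design()


@pytest.fixture(scope="session")
def bbd_responses():
    return datasets.load_bbd_responses()


@pytest.fixture(scope="session")
def bbd_specs():
    return datasets.load_bbd_factor_specs()


@pytest.fixture(scope="session")
def published_od(bbd_runs):
    return bbd_runs["od"].to_numpy(dtype=float)


# Published coefficients of the OD surface, in model order
# (const, X1, X2, X3, X1:X2, X1:X3, X2:X3, X1^2, X2^2, X3^2).
PUBLISHED_COEF = np.array([
    0.7588, -0.1362, 0.0767, -0.1491, 0.1129, -0.1476, 0.0442,
    -0.2556, -0.0907, -0.1192,
])


@pytest.fixture(scope="session")
def published_coef():
    return PUBLISHED_COEF.copy()
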