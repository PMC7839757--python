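import numpy as np
import pytest

from chwcea import load_parameters


@pytest.fixture(scope="session")
def params():
    """The packaged parameter set (published tables)."""
    return load_parameters()


@pytest.fixture(scope="session")
def utilities(params):
    return params.utilities


def assert_occupancy_valid(occupancy: np.ndarray, atol: float = 1e-9) -> None:
    assert np.all(occupancy >= -atol)
    np.testing.assert_allclose(occupancy.sum(axis=-1), 1.0, atol=atol)
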