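import numpy as np
import pytest

from wgamma import WgParams, load_dataset

PRINTED_WG_PARAMS = {
    "units30": WgParams(6.0638, 6.4448, 0.0085, 1.891),
    "components50": WgParams(5.1941, 7.5083, 0.0044, 39.4314),
    "devices30": WgParams(6.2924, 6.3784, 0.0084, 197.8811),
    "kiama": WgParams(0.7086, 4.0834, 4.6704, 3.6166),
    "egypt_tax": WgParams(0.5883, 2.8474, 16.5821, 0.5763),
}

PRINTED_WG_LOGLIK = {
    "units30": -42.1281,
    "components50": -231.7916,
    "devices30": -180.267,
    "kiama": -293.5914,
    "egypt_tax": -188.3944,
}


@pytest.fixture(scope="session")
def units30():
    return load_dataset("units30").as_array()


@pytest.fixture(scope="session")
def kiama():
    return load_dataset("kiama").as_array()


@pytest.fixture(scope="session")
def egypt_tax():
    return load_dataset("egypt_tax").as_array()


@pytest.fixture(scope="session")
def random_param_grid():
    """50 parameter vectors drawn log-uniformly from [0.2, 5]^4."""
    rng = np.random.default_rng(1234)
    draws = np.exp(rng.uniform(np.log(0.2), np.log(5.0), size=(50, 4)))
    return [WgParams(*row) for row in draws]
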