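import pytest

from oxflux.config import load_treatments
from oxflux.model import base_model_parameters, base_model_totals


@pytest.fixture(scope="session")
def base_params():
    return base_model_parameters()


@pytest.fixture(scope="session")
def base_totals():
    return base_model_totals()


@pytest.fixture(scope="session")
def treatments():
    return load_treatments()
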