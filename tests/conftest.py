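import numpy as np
import pytest

from nct.config import default_config
from nct import transport as tr


@pytest.fixture(scope="session")
def base_config():
    return default_config()


@pytest.fixture(scope="session")
def base_model(base_config):
    return tr.build_network(base_config)


@pytest.fixture(scope="session")
def nls_model(base_model):
    return tr.add_cargo(base_model, tr.NLS_SV40)


@pytest.fixture(scope="session")
def nls_steady_state(nls_model):
    return tr.steady_state(nls_model, "NLS")
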