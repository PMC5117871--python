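import numpy as np
import pytest

from nemacortex import studies
from nemacortex.synth import generate_flow_profile


@pytest.fixture(scope="session")
def ap_grid():
    return studies.ap_grid()


@pytest.fixture(scope="session")
def cytokinesis_flow_field():
    return generate_flow_profile(studies.cytokinesis_flow())


@pytest.fixture(scope="session")
def cytokinesis_truth():
    return studies.cytokinesis_truth()


@pytest.fixture(scope="session")
def pseudocleavage_flow_field():
    return generate_flow_profile(studies.pseudocleavage_flow())


@pytest.fixture(scope="session")
def pseudocleavage_truth():
    return studies.pseudocleavage_truth()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
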