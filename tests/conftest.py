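import pytest

from skincost.kc import build_kc_model
from skincost.melanoma import STAGES, build_melanoma_model
from skincost.synthetic import headline_fixture


@pytest.fixture(scope="session")
def au_fixture():
    """Calibrated AU headline parameter set and manifest."""
    return headline_fixture("AU")


@pytest.fixture(scope="session")
def nz_fixture():
    return headline_fixture("NZ")


@pytest.fixture(scope="session")
def au_params(au_fixture):
    return au_fixture[0]


@pytest.fixture(scope="session")
def nz_params(nz_fixture):
    return nz_fixture[0]


@pytest.fixture(scope="session")
def au_melanoma_models():
    return {stage: build_melanoma_model("AU", stage) for stage in STAGES}


@pytest.fixture(scope="session")
def nz_melanoma_models():
    return {stage: build_melanoma_model("NZ", stage) for stage in STAGES}


@pytest.fixture(scope="session")
def au_kc_model():
    return build_kc_model("AU")
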