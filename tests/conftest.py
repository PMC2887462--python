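import numpy as np
import pytest

from fuzzycell import (
    FitnessCriteria,
    SimulationConfig,
    build_ar_model,
    build_nfkb_model,
    build_vc_model,
    simulate,
)
from fuzzycell.analysis import OXPROT_ONLY


@pytest.fixture(scope="session")
def vc_model():
    return build_vc_model()


@pytest.fixture(scope="session")
def nfkb_model():
    return build_nfkb_model()


@pytest.fixture(scope="session")
def ar_model():
    return build_ar_model()


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def vc_run(vc_model, default_config):
    return simulate(vc_model, default_config)


@pytest.fixture(scope="session")
def nfkb_run(nfkb_model, default_config):
    return simulate(nfkb_model, default_config)


@pytest.fixture(scope="session")
def ar_run(ar_model, default_config):
    return simulate(ar_model, default_config)


@pytest.fixture(scope="session")
def three_criteria():
    return FitnessCriteria()


@pytest.fixture(scope="session")
def oxprot_criterion():
    return OXPROT_ONLY


@pytest.fixture(scope="session")
def ar_screen(ar_model):
    """The +5% rate-perturbation screen over the reference model."""
    from fuzzycell import sof_screen

    return sof_screen(ar_model, perturbation=0.05)
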