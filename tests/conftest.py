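import numpy as np
import pytest
from hypothesis import settings

import ionowave as iw

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preclinical():
    scenario, chain, acq = iw.preclinical_20mev()
    return scenario, chain, acq


@pytest.fixture(scope="session")
def clinical():
    scenario, chain, acq = iw.clinical_200mev()
    return scenario, chain, acq


@pytest.fixture(scope="session")
def clean_trace(preclinical):
    scenario, chain, acq = preclinical
    return iw.generate_clean_trace(scenario, chain, **acq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
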