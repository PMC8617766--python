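import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_panel():
    from nutrascreen import datasets

    return datasets.load_study_panel()


@pytest.fixture(scope="session")
def binding_energies():
    from nutrascreen import datasets

    return datasets.load_binding_energies()


@pytest.fixture()
def rng():
    return np.random.default_rng(20211116)
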