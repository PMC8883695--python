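import numpy as np
import pytest

from causalfpr import collider_model, confounder_model
from causalfpr.scm import COLLIDER_DAG, CONFOUNDER_DAG


@pytest.fixture
def confounder_dag():
    return CONFOUNDER_DAG


@pytest.fixture
def collider_dag():
    return COLLIDER_DAG


@pytest.fixture
def balanced_confounder():
    return confounder_model(0.25, 0.25, 0.25)


@pytest.fixture
def balanced_collider():
    return collider_model(0.25, 0.25, 0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
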