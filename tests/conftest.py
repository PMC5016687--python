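import numpy as np
import pytest

from anisofit import ResponseModel

#: Table-condition dissociation constants (M) used across tests.
APO_FRMR_K = 9.9e-8
APO_RCNR_K = 1.5e-7
NI_RCNR_K = 5.9e-6
CO_RCNR_K = 1.5e-5


@pytest.fixture
def response():
    return ResponseModel(delta_r_max=0.1)


@pytest.fixture
def trace_schedule():
    return np.linspace(0.0, 2e-6, 20)
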