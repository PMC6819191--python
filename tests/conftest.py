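import numpy as np
import pytest

import ivdratchet as ivr


@pytest.fixture
def geometry():
    return ivr.SpecimenGeometry.typical()


@pytest.fixture
def default_params():
    return ivr.SyntheticSpecimenParams()


@pytest.fixture
def protocol200():
    """The reference condition: Δσ = 1.76 MPa, 1.18 MPa/s, 200 cycles."""
    return ivr.build_protocol(1.76, 1.18, 200)


@pytest.fixture
def series200(protocol200, default_params):
    return ivr.generate_response(protocol200, default_params)


@pytest.fixture
def cycle_grid():
    return np.arange(1, 401)
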