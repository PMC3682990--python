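import pytest

from isletins import default_params, fit_hill, load_reference_secretion_data


@pytest.fixture(scope="session")
def params():
    """Default calibrated parameter set (Hill fit cached across the session)."""
    return default_params()


@pytest.fixture(scope="session")
def reference_data():
    return load_reference_secretion_data()


@pytest.fixture(scope="session")
def reference_fit(reference_data):
    return fit_hill(reference_data)


#: Small start grid for repeated fitting in Monte-Carlo tests; the surface is
#: well-behaved near the truth, so three spread starts suffice.
FAST_STARTS = ((50.0, 5.0, 2.0), (100.0, 9.0, 3.0), (150.0, 15.0, 4.0))
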