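import pytest

import phispectrum as ps


@pytest.fixture(scope="session")
def and_or():
    """AND+OR pair in state 00, exact arithmetic."""
    return ps.get_subsystem("and_or", exact=True)


@pytest.fixture(scope="session")
def and_or_float():
    return ps.get_subsystem("and_or", exact=False)


@pytest.fixture(scope="session")
def photodiode():
    return ps.get_subsystem("photodiode", exact=True)


@pytest.fixture(scope="session")
def or_and_xor():
    return ps.get_subsystem("or_and_xor", exact=True)


@pytest.fixture(scope="session")
def and_or_spectrum(and_or):
    return ps.phi_spectrum(and_or)
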