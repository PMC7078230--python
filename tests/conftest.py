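import pytest
from hypothesis import settings

import fracprey as fp

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ex71():
    return fp.example_7_1()


@pytest.fixture(scope="session")
def ex72():
    return fp.example_7_2()


@pytest.fixture(scope="session")
def ex72_literal():
    return fp.example_7_2_literal()
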