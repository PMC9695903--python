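import pytest

from tapraf import make_test_fixture


@pytest.fixture(scope="session")
def nested_raf_system():
    return make_test_fixture("nested_raf")


@pytest.fixture(scope="session")
def no_raf_system():
    return make_test_fixture("no_raf")


@pytest.fixture(scope="session")
def full_raf_system():
    return make_test_fixture("full_raf")
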