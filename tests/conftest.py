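import pytest

from metadesign import fixture


@pytest.fixture
def chain3():
    return fixture("chain3")


@pytest.fixture
def coupler6():
    return fixture("coupler6")


@pytest.fixture
def parallel2():
    return fixture("parallel2")


@pytest.fixture
def blocked1():
    return fixture("blocked1")
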