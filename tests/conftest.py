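import pytest

from palmstate import cd20_scenario, cld3_scenario


@pytest.fixture
def cld3():
    return cld3_scenario(seed=0)


@pytest.fixture
def cd20():
    return cd20_scenario(seed=0)
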