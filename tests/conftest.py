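import pytest

from stereocleave.core_stereo import SCHEMES


@pytest.fixture(params=["L1", "L2", "L3", "L4"])
def scheme(request):
    return SCHEMES[request.param]


@pytest.fixture
def l1():
    return SCHEMES["L1"]


@pytest.fixture
def l2():
    return SCHEMES["L2"]


@pytest.fixture
def l3():
    return SCHEMES["L3"]
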