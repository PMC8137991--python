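import pytest

from oct1splice import build_anchors
from oct1splice.refmodel import make_default_locus, make_toy_locus


@pytest.fixture(scope="session")
def toy_locus():
    return make_toy_locus()


@pytest.fixture(scope="session")
def locus():
    return make_default_locus()


@pytest.fixture(scope="session")
def anchors(locus):
    return build_anchors(locus)
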