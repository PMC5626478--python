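import pytest

from ctai import adaptiveness_from_map, assign_bins, build_decoding_map
from ctai.data import crd_constructs, crd_region, hek293_pool


@pytest.fixture(scope="session")
def pool():
    return hek293_pool()


@pytest.fixture(scope="session")
def partition(pool):
    return assign_bins(pool)


@pytest.fixture(scope="session")
def decoding_map(pool):
    return build_decoding_map(pool)


@pytest.fixture(scope="session")
def table(decoding_map):
    """Relative adaptiveness under default constraints (cap 80k)."""
    return adaptiveness_from_map(decoding_map)


@pytest.fixture(scope="session")
def constructs():
    return crd_constructs()


@pytest.fixture(scope="session")
def crd_span():
    return crd_region()
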