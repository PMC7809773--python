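import numpy as np
import pytest

from pprlink.matching import MatchingConfig, default_bloom_fields, default_plain_fields
from pprlink.synthetic import DatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """300-record dataset with duplicates and corruption for engine tests."""
    return generate_dataset(DatasetSpec(total=300, seed=7))


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(DatasetSpec(total=60, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def plain_matching(t=0.8):
    return MatchingConfig(tuple(default_plain_fields()), t1=t, t2=t)


def bloom_matching(t=0.85):
    return MatchingConfig(tuple(default_bloom_fields()), t1=t, t2=t)
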