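import numpy as np
import pytest

from boronmir import datasets


@pytest.fixture(scope="session")
def published_features():
    return datasets.hairpin_features()


@pytest.fixture(scope="session")
def published_counts():
    return datasets.normalized_counts()


@pytest.fixture(scope="session")
def published_calls():
    return datasets.expected_calls()


@pytest.fixture(scope="session")
def published_name_map():
    return datasets.name_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(20130326)


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
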