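import random

import pytest

from pepscreen import ScreenConfig, load_paper_fixtures

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def paper():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def config():
    return ScreenConfig()


@pytest.fixture
def rng():
    return random.Random(20210163)


def random_sequences(rng, n, max_length=50, min_length=1, alphabet=AMINO_ACIDS):
    for _ in range(n):
        length = rng.randint(min_length, max_length)
        yield "".join(rng.choice(alphabet) for _ in range(length))
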