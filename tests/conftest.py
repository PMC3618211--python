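import pytest

from ppirules.fixtures import SynthConfig, generate_corpus, worked_examples
from ppirules.lexicon import load_default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def cases():
    return worked_examples()


@pytest.fixture(scope="session")
def case_by_name(cases):
    return {c.name: c for c in cases}


@pytest.fixture(scope="session")
def small_corpus():
    """A small seeded synthetic corpus shared by read-only tests."""
    return generate_corpus(
        SynthConfig(seed=20_240_101, n_positive_relations=15, n_negative_relations=40)
    )
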