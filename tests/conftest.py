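import pytest

from fhjoint.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """40 generated documents shared by read-only tests."""
    return generate_corpus(GeneratorConfig(n_documents=40, seed=13))


@pytest.fixture(scope="session")
def clean_corpus():
    """Corpus without distractor sentences (every target has a relation)."""
    return generate_corpus(GeneratorConfig(n_documents=30, p_distractor=0.0,
                                           seed=5))
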