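import pytest

from nppairs import (
    CorpusSpec,
    build_fixture_services,
    curate_corpus,
    generate_corpus,
)


@pytest.fixture(scope="session")
def small_corpus():
    """A mid-sized synthetic corpus with default heterogeneity and no
    wrong pairs, shared across test modules."""
    return generate_corpus(
        CorpusSpec(seed=123, n_entries=300, citation_corruption_rate=0.0)
    )


@pytest.fixture(scope="session")
def small_services(small_corpus):
    return build_fixture_services(small_corpus)


@pytest.fixture(scope="session")
def small_result(small_corpus, small_services):
    return curate_corpus(small_corpus, small_services)
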