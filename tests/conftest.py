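import pytest

from pathcurate.fixtures import (
    QUERY_GENE,
    FixtureConfig,
    make_abstract_corpus,
    make_interactions,
    make_knowledgebase,
)
from pathcurate.relevance import HashedBagOfWordsEmbedder, MockJudgeProvider
from pathcurate.summarization import MockLLMProvider


@pytest.fixture(scope="session")
def cfg():
    return FixtureConfig()


@pytest.fixture(scope="session")
def kb(cfg):
    return make_knowledgebase(cfg)


@pytest.fixture(scope="session")
def interactions(cfg, kb):
    return make_interactions(cfg, kb)


@pytest.fixture(scope="session")
def corpus(cfg, kb):
    """(store, relevant_pmids, irrelevant_pmids) for the planted query gene."""
    return make_abstract_corpus(cfg, kb)


@pytest.fixture(scope="session")
def query_gene():
    return QUERY_GENE


@pytest.fixture(scope="session")
def embedder():
    return HashedBagOfWordsEmbedder()


@pytest.fixture(scope="session")
def judge():
    return MockJudgeProvider()


@pytest.fixture(scope="session")
def llm():
    return MockLLMProvider()
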