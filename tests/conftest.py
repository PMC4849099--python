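"""Shared fixtures: hand-built toy corpora and seeded synthetic benchmarks."""

from collections import Counter

import pytest

from evental import (
    ConceptSet,
    Document,
    MockKeywordLearner,
    RecognizerContract,
    Sentence,
    SynthSpec,
    generate_corpus,
)


def make_sentence(sid, tokens, gold=(), pas=(), ne_count=0):
    return Sentence(
        id=sid,
        text=" ".join(tokens),
        gold_concepts=Counter(gold),
        pas_units=list(pas),
        ne_count=ne_count,
    )


class StubLearner(RecognizerContract):
    """Recognizes a fixed set of (sentence id, concept) pairs."""

    def __init__(self, recognized=(), values=None, probs=None):
        self.recognized = set(recognized)
        self.values = values or {}
        self.probs = probs

    def train(self, labeled_documents, concept_set):
        pass

    def recognizes(self, sentence, concept):
        return (sentence.id, concept) in self.recognized

    def decision_values(self, sentence):
        return dict(self.values)

    def probabilities(self, sentence):
        return dict(self.probs) if self.probs is not None else None

    @property
    def has_probabilities(self):
        return self.probs is not None


@pytest.fixture
def two_concepts():
    return ConceptSet.from_pairs([("E1", "event"), ("E2", "event")])


@pytest.fixture
def four_sentence_corpus(two_concepts):
    """The minimal 2x2 design: feature f and concept E1 in all four combinations."""
    return [
        make_sentence("s0", ["f", "x"], gold=["E1"]),
        make_sentence("s1", ["f", "y"]),
        make_sentence("s2", ["g", "x"], gold=["E1"]),
        make_sentence("s3", ["g", "y"]),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """A fast synthetic corpus for unit-level integration tests."""
    return generate_corpus(
        SynthSpec(seed=7, n_documents=36, n_concepts=4, background_vocab_size=120)
    )


@pytest.fixture(scope="session")
def bench_corpus():
    """The benchmark-scale synthetic corpus (default generator conditions)."""
    return generate_corpus(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def bench_corpus_ner():
    return generate_corpus(SynthSpec(seed=1, concept_kind="entity"))
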