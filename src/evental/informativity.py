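"""Statistical informativity of sentences and documents for active learning.

A sentence is informative for a concept when the base recognizer does not
yet extract that concept from it; the score is then the unnormalized
Bayes product p(concept) * p(sentence | concept), where the likelihood is a
softmax over concepts of a correlation-based Z score.  Optional extras:
a participant term delta * T rewarding sentences rich in predicted
gene/protein mentions, similarity-based backoff for out-of-vocabulary
unigrams, and a linear combination of n-gram, PAS and participant terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .corpus import ConceptSet, Document, FeatureUnit, Sentence
from .learner import RecognizerContract
from .stats import CorrelationModel, probability_from_weight, softmax

__all__ = [
    "InformativityConfig",
    "PriorModel",
    "SimilarityProvider",
    "TableSimilarityProvider",
    "WordVectorSimilarityProvider",
    "load_word_vectors",
    "load_similarity_table",
    "fit_prior",
    "z_score",
    "sentence_likelihood",
    "concept_posterior",
    "concept_posteriors",
    "sentence_informativity",
    "ne_informativity",
    "oov_weight",
    "combined_sentence_informativity",
    "document_informativity",
    "InformativityScorer",
]

PRIOR_FLOOR = 1e-6


@dataclass(frozen=True)
class InformativityConfig:
    """Tunable weights of the informativity estimator.

    Defaults are the tuned operating point: participant weight delta=0.25,
    combination weights (alpha, beta, gamma)=(0.1, 0.1, 0.8) on the n-gram,
    PAS and participant terms, and k=25 similarity neighbors for OOV backoff.
    """

    delta: float = 0.25
    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 0.8
    k: int = 25
    feature_kind: str = "ngram"  # "ngram" | "pas" | "combined"
    ngram_order: int | frozenset = 1
    oov_enabled: bool = False
    method: str = "chi2_yates"

    def __post_init__(self) -> None:
        if self.delta < 0 or min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("weights must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.feature_kind not in ("ngram", "pas", "combined"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")


@dataclass(frozen=True)
class PriorModel:
    """MLE concept prior from sentence-level annotation counts."""

    probabilities: dict[str, float]

    def __getitem__(self, concept: str) -> float:
        return self.probabilities[concept]


def fit_prior(
    labeled_sentences: Sequence[Sentence], concept_set: ConceptSet
) -> PriorModel:
    """p(concept) = annotated-sentence count / total, with an epsilon floor.

    Concepts never annotated receive a count floor of 1e-6 before
    normalization so their posterior stays positive.
    """
    counts = {c: 0.0 for c in concept_set.ids}
    total_raw = 0
    for sent in labeled_sentences:
        for c in set(sent.gold_concepts):
            if c in counts:
                counts[c] += 1
                total_raw += 1
    if total_raw == 0:
        raise RuntimeError("no annotations in the labeled pool; cannot fit prior")
    floored = {c: (n if n > 0 else PRIOR_FLOOR) for c, n in counts.items()}
    z = sum(floored.values())
    return PriorModel({c: n / z for c, n in floored.items()})


class SimilarityProvider(Protocol):
    """Word-similarity resource used for out-of-vocabulary backoff."""

    def similarity(self, w1: str, w2: str) -> float: ...

    def top_k(self, word: str, k: int, within: set[str]) -> list[tuple[str, float]]:
        """Top-k words from ``within`` most similar to ``word`` (desc, ties by word)."""
        ...


@dataclass
class TableSimilarityProvider:
    """Similarity from an explicit symmetric pair table."""

    pairs: dict[tuple[str, str], float]

    def similarity(self, w1: str, w2: str) -> float:
        if w1 == w2:
            return 1.0
        return self.pairs.get((w1, w2), self.pairs.get((w2, w1), 0.0))

    def known(self, word: str) -> set[str]:
        out = set()
        for a, b in self.pairs:
            if a == word:
                out.add(b)
            elif b == word:
                out.add(a)
        return out

    def top_k(self, word: str, k: int, within: set[str]) -> list[tuple[str, float]]:
        cands = [(w, self.similarity(word, w)) for w in (self.known(word) & within)]
        cands.sort(key=lambda t: (-t[1], t[0]))
        return cands[:k]


@dataclass
class WordVectorSimilarityProvider:
    """Cosine similarity over a dense word-vector table."""

    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w, v in self.vectors.items():
            n = np.linalg.norm(v)
            if n > 0:
                self.vectors[w] = v / n

    def similarity(self, w1: str, w2: str) -> float:
        v1, v2 = self.vectors.get(w1), self.vectors.get(w2)
        if v1 is None or v2 is None:
            return 0.0
        return float(np.dot(v1, v2))

    def top_k(self, word: str, k: int, within: set[str]) -> list[tuple[str, float]]:
        if word not in self.vectors:
            return []
        cands = [
            (w, self.similarity(word, w)) for w in within if w in self.vectors
        ]
        cands.sort(key=lambda t: (-t[1], t[0]))
        return cands[:k]


def load_word_vectors(path: Path | str) -> WordVectorSimilarityProvider:
    """Read text-format word vectors: header ``count dim``, then ``word v1..vd``."""
    lines = Path(path).read_text().split("\n")
    count, dim = (int(x) for x in lines[0].split())
    vectors = {}
    for line in lines[1 : count + 1]:
        parts = line.split()
        if len(parts) != dim + 1:
            raise ValueError(f"expected {dim} components for word {parts[:1]}")
        vectors[parts[0]] = np.asarray([float(x) for x in parts[1:]])
    return WordVectorSimilarityProvider(vectors)


def load_similarity_table(path: Path | str) -> TableSimilarityProvider:
    """Read pairwise similarities: tab-separated ``w1 w2 sim`` lines."""
    pairs = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            w1, w2, s = line.split("\t")
            pairs[(w1, w2)] = float(s)
    return TableSimilarityProvider(pairs)


# ---------------------------------------------------------------------------
# Core estimator
# ---------------------------------------------------------------------------

def oov_weight(
    word: str,
    concept: str,
    model: CorrelationModel,
    sim: SimilarityProvider,
    k: int = 25,
) -> float:
    """Backoff weight for an out-of-vocabulary unigram.

    Sum over the top-k in-vocabulary neighbors of W(neighbor, concept) times
    the similarity; 0 when the provider knows no in-vocabulary neighbor.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total = 0.0
    for nb, s in sim.top_k(word, k, model.unigram_vocabulary()):
        w = model.weights.get((FeatureUnit("ngram", (nb,)), concept))
        if w is not None:
            total += w * s
    return total


def z_score(
    sentence: Sentence,
    concept: str,
    model: CorrelationModel,
    sim: SimilarityProvider | None = None,
    k: int = 25,
    oov_enabled: bool = False,
) -> float:
    """Length-normalized sum of p(feature | concept) over feature occurrences.

    Zero-length sentences score 0.  With OOV backoff enabled, unknown
    unigrams contribute the softmax-converted backoff weight; other unknown
    features contribute 0.
    """
    length = sentence.word_count
    if length == 0:
        return 0.0
    total = 0.0
    for f, mult in model.features(sentence).items():
        w = model.weights.get((f, concept))
        if w is None:
            if (
                oov_enabled
                and sim is not None
                and f.kind == "ngram"
                and len(f.value) == 1
            ):
                w_oov = oov_weight(f.value[0], concept, model, sim, k)
                total += mult * probability_from_weight(model, w_oov, concept)
            continue
        total += mult * probability_from_weight(model, w, concept)
    return total / length


def sentence_likelihood(
    sentence: Sentence,
    concept_set: ConceptSet,
    model: CorrelationModel,
    sim: SimilarityProvider | None = None,
    k: int = 25,
    oov_enabled: bool = False,
) -> dict[str, float]:
    """p(sentence | concept): softmax over the concept set of the Z scores."""
    if len(concept_set) == 0:
        raise ValueError("empty concept set")
    zs = {
        c: z_score(sentence, c, model, sim=sim, k=k, oov_enabled=oov_enabled)
        for c in concept_set.ids
    }
    return softmax(zs)


def concept_posteriors(
    sentence: Sentence,
    concept_set: ConceptSet,
    prior: PriorModel,
    model: CorrelationModel,
    sim: SimilarityProvider | None = None,
    k: int = 25,
    oov_enabled: bool = False,
) -> dict[str, float]:
    """Unnormalized Bayes scores p(concept) * p(sentence | concept) per concept.

    The sentence evidence term is treated as the constant 1: the scores are
    used only to rank, and normalizing them per sentence would give every
    fully-unrecognized sentence the same total.
    """
    lik = sentence_likelihood(
        sentence, concept_set, model, sim=sim, k=k, oov_enabled=oov_enabled
    )
    return {c: prior[c] * lik[c] for c in concept_set.ids}


def concept_posterior(
    sentence: Sentence,
    concept: str,
    concept_set: ConceptSet,
    prior: PriorModel,
    model: CorrelationModel,
) -> float:
    return concept_posteriors(sentence, concept_set, prior, model)[concept]


def sentence_informativity(
    sentence: Sentence,
    concept_set: ConceptSet,
    learner: RecognizerContract,
    prior: PriorModel,
    model: CorrelationModel,
    sim: SimilarityProvider | None = None,
    k: int = 25,
    oov_enabled: bool = False,
) -> float:
    """Sum of posteriors over concepts the learner does NOT recognize here.

    A concept the current base model already extracts from the sentence
    contributes exactly 0 (annotating it would teach the model nothing new).
    """
    post = concept_posteriors(
        sentence, concept_set, prior, model, sim=sim, k=k, oov_enabled=oov_enabled
    )
    return sum(
        0.0 if learner.recognizes(sentence, c) else post[c] for c in concept_set.ids
    )


def ne_informativity(sentence: Sentence, delta: float) -> float:
    """Participant term: delta * (number of predicted entity mentions)."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return delta * sentence.ne_count


def combined_sentence_informativity(
    sentence: Sentence,
    concept_set: ConceptSet,
    config: InformativityConfig,
    learner: RecognizerContract,
    prior: PriorModel,
    ngram_model: CorrelationModel | None = None,
    pas_model: CorrelationModel | None = None,
    sim: SimilarityProvider | None = None,
) -> float:
    """alpha * I_ngram (with optional OOV backoff) + beta * I_pas + gamma * delta * T."""
    total = 0.0
    if config.alpha > 0:
        if ngram_model is None:
            raise RuntimeError("alpha > 0 requires a fitted n-gram model")
        total += config.alpha * sentence_informativity(
            sentence,
            concept_set,
            learner,
            prior,
            ngram_model,
            sim=sim,
            k=config.k,
            oov_enabled=config.oov_enabled,
        )
    if config.beta > 0:
        if pas_model is None:
            raise RuntimeError("beta > 0 requires a fitted PAS model")
        total += config.beta * sentence_informativity(
            sentence, concept_set, learner, prior, pas_model
        )
    if config.gamma > 0:
        total += config.gamma * ne_informativity(sentence, config.delta)
    return total


def document_informativity(document: Document, scorer) -> float:
    """Mean sentence score over the document (size-normalized)."""
    if document.size < 1:
        raise ValueError(f"document {document.id} has no sentences")
    return sum(scorer(s) for s in document.sentences) / document.size


@dataclass
class InformativityScorer:
    """Bundle of fitted models implementing the full combined score."""

    concept_set: ConceptSet
    config: InformativityConfig
    learner: RecognizerContract
    prior: PriorModel
    ngram_model: CorrelationModel | None = None
    pas_model: CorrelationModel | None = None
    sim: SimilarityProvider | None = None

    def sentence_score(self, sentence: Sentence) -> float:
        return combined_sentence_informativity(
            sentence,
            self.concept_set,
            self.config,
            self.learner,
            self.prior,
            ngram_model=self.ngram_model,
            pas_model=self.pas_model,
            sim=self.sim,
        )

    def document_score(self, document: Document) -> float:
        return document_informativity(document, self.sentence_score)
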