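"""Document-ranking strategies for pool-based active learning.

Five selectors over the unlabeled pool: the proposed informativity score,
conventional two-member committee disagreement, entropy-based and
Gibbs-error-based uncertainty sampling, and seeded random selection.  All
deterministic rankings break ties by ascending document id.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .corpus import ConceptSet, Document, Sentence
from .informativity import (
    InformativityScorer,
    PriorModel,
    concept_posteriors,
)
from .learner import RecognizerContract, difference2_confidence
from .stats import CorrelationModel, feature_probability, softmax

__all__ = [
    "rank_informativity",
    "binary_entropy",
    "entropy_document_score",
    "gibbs_document_score",
    "committee_disagreement",
    "rank_by_score",
    "random_ranking",
]


def rank_by_score(documents: Sequence[Document], score_fn) -> list[Document]:
    """Descending by score, ties by ascending document id."""
    return sorted(documents, key=lambda d: (-score_fn(d), d.id))


def rank_informativity(
    documents: Sequence[Document], scorer: InformativityScorer
) -> list[Document]:
    """Order the pool by descending document informativity."""
    return rank_by_score(documents, scorer.document_score)


def binary_entropy(p: float) -> float:
    """-p*log2(p) - (1-p)*log2(1-p), in bits, with 0*log0 = 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    h = 0.0
    if p > 0:
        h -= p * math.log2(p)
    if p < 1:
        h -= (1 - p) * math.log2(1 - p)
    return h


def _concept_given_feature(
    f, concept_set: ConceptSet, model: CorrelationModel, prior: PriorModel
) -> dict[str, float] | None:
    """p(concept | feature) by Bayes over the concept set; None if OOV."""
    if (f, concept_set.ids[0]) not in model.weights:
        return None
    raw = {
        c: prior[c] * feature_probability(model, f, c) for c in concept_set.ids
    }
    z = sum(raw.values())
    if z == 0:
        return None
    return {c: v / z for c, v in raw.items()}


def _uncertainty_score(
    document: Document,
    concept_set: ConceptSet,
    model: CorrelationModel,
    prior: PriorModel,
    kernel,
) -> float:
    """Sum over sentences of (1/len) * sum over n-gram occurrences and
    concepts of kernel(p(concept | n-gram)); OOV n-grams are skipped."""
    total = 0.0
    for sent in document.sentences:
        if sent.word_count == 0:
            continue
        acc = 0.0
        for f, mult in model.features(sent).items():
            probs = _concept_given_feature(f, concept_set, model, prior)
            if probs is None:
                continue
            acc += mult * sum(kernel(p) for p in probs.values())
        total += acc / sent.word_count
    return total


def entropy_document_score(
    document: Document,
    concept_set: ConceptSet,
    model: CorrelationModel,
    prior: PriorModel,
) -> float:
    """Summed per-sentence average n-gram label entropy (bits)."""
    return _uncertainty_score(document, concept_set, model, prior, binary_entropy)


def gibbs_document_score(
    document: Document,
    concept_set: ConceptSet,
    model: CorrelationModel,
    prior: PriorModel,
) -> float:
    """Same nesting as the entropy score with the Gibbs kernel 1 - p**2."""
    return _uncertainty_score(
        document, concept_set, model, prior, lambda p: 1.0 - p * p
    )


def committee_disagreement(
    document: Document,
    concept_set: ConceptSet,
    learner: RecognizerContract,
    prior: PriorModel,
    model: CorrelationModel,
) -> float:
    """Two-member committee disagreement between the statistical estimator
    and the base recognizer.

    Per sentence and concept, the absolute difference between the
    informativity posterior (computed for every sentence, without the
    recognized-concept filter) and the recognizer's probability: the
    system's own calibrated probability when it exposes one, otherwise the
    softmax over concepts of the difference-2 margin confidence.
    """
    total = 0.0
    for sent in document.sentences:
        p_inf = concept_posteriors(sent, concept_set, prior, model)
        p_learner = learner.probabilities(sent)
        if p_learner is None:
            values = learner.decision_values(sent)
            if not values:
                raise RuntimeError(
                    "recognizer provides neither probabilities nor decision values"
                )
            conf = difference2_confidence(values)
            p_learner = softmax({c: conf for c in concept_set.ids})
        total += sum(
            abs(p_inf[c] - p_learner.get(c, 0.0)) for c in concept_set.ids
        )
    return total


def random_ranking(documents: Sequence[Document], seed: int) -> list[Document]:
    """Uniform random permutation, reproducible per seed."""
    docs = sorted(documents, key=lambda d: d.id)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    return [docs[i] for i in order]
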