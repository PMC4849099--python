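"""Base-recognizer contract and a trainable mock keyword recognizer.

Real pipelines plug an event-extraction or NER system in behind
:class:`RecognizerContract` (an adapter must implement ``train``,
``recognizes``, ``decision_values`` and ``ne_count``, and may expose
calibrated per-concept ``probabilities``).  The bundled
:class:`MockKeywordLearner` learns concept-keyword co-occurrence counts from
the labeled pool, which is enough to drive closed-loop simulations: its
accuracy genuinely improves as more documents are labeled.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from collections import Counter, defaultdict
from typing import Mapping, Sequence

__all__ = ["RecognizerContract", "MockKeywordLearner", "difference2_confidence"]


class RecognizerContract(ABC):
    """Behavioral contract for the underlying recognizer.

    ``recognizes`` must be consistent with the sign convention of
    ``decision_values`` (here: value >= 0 means recognized).
    ``probabilities`` returns per-concept probabilities when the system can
    provide them (e.g. CRF marginals) and ``None`` otherwise.
    """

    @abstractmethod
    def train(self, labeled_documents: Sequence, concept_set) -> None: ...

    @abstractmethod
    def recognizes(self, sentence, concept: str) -> bool: ...

    @abstractmethod
    def decision_values(self, sentence) -> dict[str, float]: ...

    def probabilities(self, sentence) -> dict[str, float] | None:
        return None

    @property
    def has_probabilities(self) -> bool:
        return False

    def ne_count(self, sentence) -> int:
        return sentence.ne_count


class MockKeywordLearner(RecognizerContract):
    """Deterministic keyword-count recognizer.

    Training counts, per concept, the number of labeled sentences in which
    each token co-occurs with an annotation of that concept.  A concept is
    recognized in a sentence iff some token of the sentence reached the
    recognition threshold during training.  The decision value is
    (max co-count over the sentence's tokens) - threshold, so recognition
    corresponds to a non-negative decision value.

    The default threshold of 6 keeps the recognizer unsaturated at
    benchmark-corpus scale: it must exceed the chance co-occurrence count a
    background token accumulates with any one concept over the whole pool
    (about 1 under the default generator), or precision collapses as the
    labeled pool grows.
    """

    def __init__(self, threshold: int = 6, expose_probabilities: bool = False):
        if threshold < 1:
            raise ValueError("threshold must be >= 1")
        self.threshold = threshold
        self.expose_probabilities = expose_probabilities
        self.counts: dict[str, Counter] = defaultdict(Counter)
        self.concept_ids: tuple[str, ...] = ()
        self._trained = False

    def train(self, labeled_documents: Sequence, concept_set) -> None:
        self.counts = defaultdict(Counter)
        self.concept_ids = tuple(concept_set.ids)
        for doc in labeled_documents:
            for sent in doc.sentences:
                toks = set(sent.tokens)
                for concept in set(sent.gold_concepts):
                    if concept in concept_set:
                        for tok in toks:
                            self.counts[concept][tok] += 1
        self._trained = True

    def recognizes(self, sentence, concept: str) -> bool:
        counts = self.counts.get(concept)
        if not counts:
            return False
        return any(counts.get(t, 0) >= self.threshold for t in set(sentence.tokens))

    def decision_values(self, sentence) -> dict[str, float]:
        toks = set(sentence.tokens)
        concepts = self.concept_ids or tuple(self.counts)
        out = {}
        for concept in concepts:
            counts = self.counts.get(concept, {})
            best = max((counts.get(t, 0) for t in toks), default=0)
            out[concept] = float(best - self.threshold)
        return out

    def probabilities(self, sentence) -> dict[str, float] | None:
        if not self.expose_probabilities:
            return None
        from .stats import softmax  # local import to avoid a cycle

        values = self.decision_values(sentence)
        return softmax(values) if values else None

    @property
    def has_probabilities(self) -> bool:
        return self.expose_probabilities

    def serialize(self) -> str:
        lines = []
        for concept in sorted(self.counts):
            for tok, n in sorted(self.counts[concept].items()):
                lines.append(f"{concept}\t{tok}\t{n}")
        return "".join(l + "\n" for l in lines)


def difference2_confidence(
    values: Mapping[str, float], target_concept: str | None = None
) -> float:
    """SVM margin heuristic: best decision value minus the runner-up.

    The quantity is a property of the whole sentence (it does not depend on
    ``target_concept``, which is accepted for interface symmetry).  With a
    single concept the value itself is returned.
    """
    if not values:
        raise ValueError("empty decision-value mapping")
    ranked = sorted(values.values(), reverse=True)
    if len(ranked) == 1:
        return ranked[0]
    return ranked[0] - ranked[1]
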