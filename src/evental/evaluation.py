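"""Learning-curve bookkeeping, the deficiency metric, and the sentence-level
top-N concept-prediction accuracy used for parameter screening.

Deficiency summarizes a 10-round learning curve against a reference curve
(in practice: averaged random selection); values below 1 mean the active
learning strategy reached the reference's final quality faster.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus import ConceptSet, Document, Sentence
from .informativity import PriorModel, concept_posteriors
from .learner import RecognizerContract
from .stats import CorrelationModel

__all__ = [
    "LearningCurve",
    "deficiency",
    "average_curves",
    "concept_prediction_accuracy",
    "recognition_f1",
    "write_curve",
    "read_curve",
]


@dataclass(frozen=True)
class LearningCurve:
    """Per-round scores of the base recognizer on the fixed test split."""

    scores: tuple[float, ...]
    n_labeled: tuple[int, ...] = ()
    strategy: str = ""

    def __post_init__(self) -> None:
        if self.n_labeled and len(self.n_labeled) != len(self.scores):
            raise ValueError("n_labeled and scores must have equal length")

    @property
    def n(self) -> int:
        return len(self.scores)


def deficiency(al: LearningCurve, ref: LearningCurve) -> float:
    """sum_t (ref_n - al_t) / sum_t (ref_n - ref_t) over rounds t=1..n.

    Scale- and shift-invariant in the common accuracy units; requires a
    non-flat reference curve.
    """
    if al.n != ref.n:
        raise ValueError(f"curve length mismatch: {al.n} != {ref.n}")
    if al.n < 2:
        raise ValueError("deficiency needs curves of at least 2 rounds")
    final = ref.scores[-1]
    denom = sum(final - s for s in ref.scores)
    if denom == 0:
        raise ZeroDivisionError("flat reference curve: deficiency undefined")
    num = sum(final - s for s in al.scores)
    return num / denom


def average_curves(curves: Sequence[LearningCurve], strategy: str = "") -> LearningCurve:
    """Round-wise mean of equal-length curves (e.g. the RS_Average baseline)."""
    if not curves:
        raise ValueError("no curves to average")
    n = curves[0].n
    if any(c.n != n for c in curves):
        raise ValueError("curves must have equal length")
    scores = tuple(sum(c.scores[t] for c in curves) / len(curves) for t in range(n))
    n_labeled = curves[0].n_labeled if curves[0].n_labeled else ()
    return LearningCurve(scores=scores, n_labeled=n_labeled, strategy=strategy)


def concept_prediction_accuracy(
    sentences: Sequence[Sentence],
    concept_set: ConceptSet,
    model: CorrelationModel,
    prior: PriorModel,
) -> float:
    """Mean per-sentence overlap of the top-N predicted concepts with gold.

    For each sentence with N >= 1 distinct gold concepts, concepts are ranked
    by the Bayes score prior * likelihood (ties by identifier) and the top-N
    are compared with gold; sentences without gold concepts are skipped.
    """
    scores = []
    for sent in sentences:
        gold = set(sent.gold_concepts) & set(concept_set.ids)
        if not gold:
            continue
        post = concept_posteriors(sent, concept_set, prior, model)
        ranked = sorted(concept_set.ids, key=lambda c: (-post[c], c))
        top = set(ranked[: len(gold)])
        scores.append(len(top & gold) / len(gold))
    if not scores:
        raise ValueError("no sentence carries gold concepts")
    return sum(scores) / len(scores)


def recognition_f1(
    learner: RecognizerContract,
    documents: Sequence[Document],
    concept_set: ConceptSet,
) -> float:
    """Sentence-level micro-F1 of concept recognition.

    Each (sentence, concept) pair is one binary decision: gold presence vs.
    the recognizer's verdict.  Returns 1.0 when there is nothing to find and
    nothing was predicted.
    """
    tp = fp = fn = 0
    for doc in documents:
        for sent in doc.sentences:
            gold = set(sent.gold_concepts) & set(concept_set.ids)
            for c in concept_set.ids:
                pred = learner.recognizes(sent, c)
                if pred and c in gold:
                    tp += 1
                elif pred:
                    fp += 1
                elif c in gold:
                    fn += 1
    if tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)


def write_curve(curve: LearningCurve, path: Path | str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["round", "n_labeled", "score"])
        n_labeled = curve.n_labeled or tuple([0] * curve.n)
        for t, (nl, s) in enumerate(zip(n_labeled, curve.scores), start=1):
            w.writerow([t, nl, repr(s)])


def read_curve(path: Path | str, strategy: str = "") -> LearningCurve:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != ["round", "n_labeled", "score"]:
        raise ValueError(f"{path}: malformed learning-curve CSV header")
    if len(rows) == 1:
        raise ValueError(f"{path}: curve has no data rows")
    scores, n_labeled = [], []
    for row in rows[1:]:
        if len(row) != 3:
            raise ValueError(f"{path}: malformed row {row!r}")
        n_labeled.append(int(row[1]))
        scores.append(float(row[2]))
    return LearningCurve(
        scores=tuple(scores), n_labeled=tuple(n_labeled), strategy=strategy
    )
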