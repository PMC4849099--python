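"""Feature-concept association statistics on sentence-level 2x2 tables.

For each (feature unit, concept) pair a contingency table counts sentences
cross-classified by "contains the feature" and "expresses the concept"
(presence, not multiplicity, on both axes).  Three association measures turn
the table into a ranking weight W: Yates' continuity-corrected chi-square,
relative risk, and the odds ratio.  W values are converted to probabilities
p(feature | concept) by a softmax over the training vocabulary.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from scipy.special import logsumexp

from .corpus import ConceptSet, FeatureUnit, Sentence, sentence_features

__all__ = [
    "ContingencyTable",
    "DegenerateTableError",
    "CorrelationModel",
    "build_tables",
    "yates_chi_square",
    "relative_risk",
    "odds_ratio",
    "softmax",
    "fit_correlation_model",
    "feature_probability",
    "CORRELATION_METHODS",
]


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero marginal where the statistic is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """Sentence counts: a=(feature, concept), b=(feature, no concept),
    c=(no feature, concept), d=(no feature, no concept)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_a(self) -> int:  # feature present
        return self.a + self.b

    @property
    def n_b(self) -> int:  # feature absent
        return self.c + self.d

    @property
    def n_s(self) -> int:  # concept expressed
        return self.a + self.c

    @property
    def n_f(self) -> int:  # concept not expressed
        return self.b + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def yates_chi_square(t: ContingencyTable, clamp: bool = False) -> float:
    """Yates' continuity-corrected chi-square, N*(|ad-bc| - N/2)^2 / (Ns*Nf*Na*Nb).

    With ``clamp=True`` the corrected difference is floored at 0 (the
    textbook variant); the default squares (|ad-bc| - N/2) as-is even when
    the correction overshoots.
    """
    if min(t.n_s, t.n_f, t.n_a, t.n_b) == 0:
        raise DegenerateTableError(f"zero marginal in table {t}")
    diff = abs(t.a * t.d - t.b * t.c) - t.n / 2
    if clamp:
        diff = max(diff, 0.0)
    return t.n * diff * diff / (t.n_s * t.n_f * t.n_a * t.n_b)


def _haldane(t: ContingencyTable) -> float:
    if t.n == 0:
        raise DegenerateTableError("all-zero table")
    return 0.5 if min(t.a, t.b, t.c, t.d) == 0 else 0.0


def relative_risk(t: ContingencyTable) -> float:
    """(a/(a+b)) / (c/(c+d)); Haldane-Anscombe +0.5 on all cells iff any is 0."""
    h = _haldane(t)
    return ((t.a + h) / (t.a + t.b + 2 * h)) / ((t.c + h) / (t.c + t.d + 2 * h))


def odds_ratio(t: ContingencyTable) -> float:
    """(a*d) / (b*c); Haldane-Anscombe +0.5 on all cells iff any is 0."""
    h = _haldane(t)
    return ((t.a + h) * (t.d + h)) / ((t.b + h) * (t.c + h))


CORRELATION_METHODS: dict[str, Callable[[ContingencyTable], float]] = {
    "chi2_yates": yates_chi_square,
    "relative_risk": relative_risk,
    "odds_ratio": odds_ratio,
}


def softmax(scores: Mapping) -> dict:
    """Shift-invariant softmax of a score mapping; values sum to 1."""
    if not scores:
        raise ValueError("softmax of an empty mapping")
    m = max(scores.values())
    exps = {k: math.exp(v - m) for k, v in scores.items()}
    z = sum(exps.values())
    return {k: v / z for k, v in exps.items()}


def build_tables(
    labeled_sentences: Sequence[Sentence],
    concept_set: ConceptSet,
    feature_fn: Callable[[Sentence], Iterable[FeatureUnit]],
) -> dict[tuple[FeatureUnit, str], ContingencyTable]:
    """2x2 tables for every (observed feature, concept) pair.

    Feature presence and concept expression are binary per sentence; the four
    cells of each table partition the sentence list.
    """
    n = len(labeled_sentences)
    feat_count: Counter = Counter()
    conc_count: Counter = Counter()
    joint: Counter = Counter()
    for sent in labeled_sentences:
        feats = set(feature_fn(sent))
        concs = set(sent.gold_concepts) & set(concept_set.ids)
        for f in feats:
            feat_count[f] += 1
        for c in concs:
            conc_count[c] += 1
        for f in feats:
            for c in concs:
                joint[(f, c)] += 1
    tables = {}
    for f, nf in feat_count.items():
        for c in concept_set.ids:
            a = joint.get((f, c), 0)
            nc = conc_count.get(c, 0)
            tables[(f, c)] = ContingencyTable(
                a=a, b=nf - a, c=nc - a, d=n - nf - nc + a
            )
    return tables


@dataclass
class CorrelationModel:
    """Fitted W(feature, concept) weights plus per-concept softmax normalizers.

    ``feature_kind``/``ngram_order`` record how sentence features were
    extracted so scoring uses the same representation as fitting.
    """

    method: str
    feature_kind: str
    ngram_order: int | frozenset
    weights: dict[tuple[FeatureUnit, str], float]
    concepts: tuple[str, ...]
    log_norm: dict[str, float]

    @property
    def vocabulary(self) -> set[FeatureUnit]:
        return {f for f, _ in self.weights}

    def features(self, sentence: Sentence) -> Counter:
        return sentence_features(sentence, self.feature_kind, self.ngram_order)

    def unigram_vocabulary(self) -> set[str]:
        """In-vocabulary unigram strings (for OOV neighbor lookups)."""
        return {
            f.value[0]
            for f in self.vocabulary
            if f.kind == "ngram" and len(f.value) == 1
        }

    def weight(self, f: FeatureUnit, concept: str) -> float | None:
        return self.weights.get((f, concept))

    def save(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.method}\t{self.feature_kind}\t{_order_repr(self.ngram_order)}\n")
            for (f, c), w in sorted(
                self.weights.items(), key=lambda kv: (kv[0][0].kind, kv[0][0].value, kv[0][1])
            ):
                fh.write(f"{f.kind}:{','.join(f.value)}\t{c}\t{w!r}\n")

    @classmethod
    def load(cls, path: Path | str) -> "CorrelationModel":
        lines = Path(path).read_text().splitlines()
        method, feature_kind, order_s = lines[0].split("\t")
        order: int | frozenset
        order = (
            frozenset(int(x) for x in order_s.split("+"))
            if "+" in order_s
            else int(order_s)
        )
        weights = {}
        for line in lines[1:]:
            feat_s, c, w = line.split("\t")
            kind, value_s = feat_s.split(":", 1)
            weights[(FeatureUnit(kind, tuple(value_s.split(","))), c)] = float(w)
        concepts = tuple(sorted({c for _, c in weights}))
        return cls(
            method=method,
            feature_kind=feature_kind,
            ngram_order=order,
            weights=weights,
            concepts=concepts,
            log_norm=_log_normalizers(weights, concepts),
        )


def _order_repr(order: int | frozenset) -> str:
    if isinstance(order, int):
        return str(order)
    return "+".join(str(x) for x in sorted(order))


def _log_normalizers(
    weights: Mapping[tuple[FeatureUnit, str], float], concepts: Sequence[str]
) -> dict[str, float]:
    per_concept: dict[str, list[float]] = {c: [] for c in concepts}
    for (_, c), w in weights.items():
        per_concept[c].append(w)
    return {
        c: float(logsumexp(ws)) if ws else math.inf for c, ws in per_concept.items()
    }


def fit_correlation_model(
    labeled_sentences: Sequence[Sentence],
    concept_set: ConceptSet,
    method: str = "chi2_yates",
    feature_kind: str = "ngram",
    ngram_order: int | Iterable[int] = 1,
    clamp_chi2: bool = False,
) -> CorrelationModel:
    """Fit W(feature, concept) for every feature observed in the labeled pool.

    Tables where the chosen statistic is degenerate (a zero marginal for
    chi-square, an empty pool for the ratio measures) contribute W=0.
    """
    if method not in CORRELATION_METHODS:
        raise ValueError(
            f"unknown correlation method {method!r}; choose from {sorted(CORRELATION_METHODS)}"
        )
    if not labeled_sentences:
        raise ValueError("cannot fit a correlation model on an empty sentence list")
    order = ngram_order if isinstance(ngram_order, int) else frozenset(ngram_order)
    tables = build_tables(
        labeled_sentences,
        concept_set,
        lambda s: sentence_features(s, feature_kind, order),
    )
    stat = CORRELATION_METHODS[method]
    weights = {}
    for key, table in tables.items():
        try:
            if method == "chi2_yates":
                w = yates_chi_square(table, clamp=clamp_chi2)
            else:
                w = stat(table)
        except DegenerateTableError:
            w = 0.0
        weights[key] = float(w)
    concepts = concept_set.ids
    return CorrelationModel(
        method=method,
        feature_kind=feature_kind,
        ngram_order=order,
        weights=weights,
        concepts=concepts,
        log_norm=_log_normalizers(weights, concepts),
    )


def feature_probability(model: CorrelationModel, f: FeatureUnit, concept: str) -> float:
    """p(feature | concept): softmax of W over the training vocabulary.

    Out-of-vocabulary features score 0 here; similarity-based backoff is a
    separate, opt-in path.
    """
    w = model.weights.get((f, concept))
    if w is None:
        return 0.0
    return probability_from_weight(model, w, concept)


def probability_from_weight(model: CorrelationModel, w: float, concept: str) -> float:
    """Convert a raw weight to a probability with the concept's cached normalizer."""
    ln = model.log_norm.get(concept)
    if ln is None:
        raise KeyError(f"concept {concept!r} not in fitted model")
    if math.isinf(ln):
        return 0.0
    return math.exp(w - ln)
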