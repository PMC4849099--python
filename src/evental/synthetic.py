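"""Seeded synthetic annotated corpora with planted concept-keyword structure.

The generator emulates the statistical shape the selection method relies
on, at abstract scale: a multi-concept ontology where each concept owns a
small trigger vocabulary; sentences that express a concept embed its
keywords among background noise tokens; entity mentions are planted at a
higher rate in concept-bearing sentences; PAS units are proxied by
adjacent-token pairs; and a fraction of each concept's keywords can be held
out of the training splits to create genuine out-of-vocabulary words in the
test split, paired with a similarity provider that knows they resemble the
retained keywords of the same concept.

It makes no attempt at linguistic realism: token frequencies are uniform,
not Zipfian, and sentences have no syntax.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import (
    ConceptSet,
    Document,
    Sentence,
    write_concept_set,
    write_standoff_corpus,
)
from .informativity import TableSimilarityProvider

__all__ = [
    "SynthSpec",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_similarity_provider",
    "split_heldout",
]


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters; the defaults define the benchmark conditions.

    10 concepts with 5 keywords each over a 500-word background vocabulary,
    200 abstract-sized documents of 3-8 sentences, keyword emission
    probability 0.9 per expressed concept.
    """

    seed: int
    n_concepts: int = 10
    keywords_per_concept: int = 5
    background_vocab_size: int = 500
    n_documents: int = 200
    sentences_per_document: tuple[int, int] = (3, 8)
    tokens_per_sentence: tuple[int, int] = (6, 12)
    concept_probability: float = 0.6
    second_concept_probability: float = 0.25
    keyword_emission: float = 0.9
    ne_rate_concept: float = 0.4
    ne_rate_background: float = 0.05
    oov_holdout_fraction: float = 0.0
    concept_kind: str = "event"  # "event" | "relation" | "entity"

    def __post_init__(self) -> None:
        probs = (
            self.concept_probability,
            self.second_concept_probability,
            self.keyword_emission,
            self.ne_rate_concept,
            self.ne_rate_background,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.oov_holdout_fraction < 1:
            raise ValueError("oov_holdout_fraction must lie in [0, 1)")
        sizes = (
            self.n_concepts,
            self.keywords_per_concept,
            self.background_vocab_size,
            self.n_documents,
        )
        if any(s < 1 for s in sizes):
            raise ValueError("sizes must be >= 1")
        for lo, hi in (self.sentences_per_document, self.tokens_per_sentence):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")
        if self.concept_kind not in ("event", "relation", "entity"):
            raise ValueError(f"unknown concept kind {self.concept_kind!r}")


@dataclass
class SyntheticCorpus:
    concept_set: ConceptSet
    dev: list[Document]
    train: list[Document]
    test: list[Document]
    keyword_map: dict[str, list[str]]
    heldout_map: dict[str, list[str]]
    spec: SynthSpec

    @property
    def all_documents(self) -> list[Document]:
        return self.dev + self.train + self.test


def _concept_ids(spec: SynthSpec) -> list[str]:
    prefix = {"event": "E", "relation": "R", "entity": "N"}[spec.concept_kind]
    return [f"{prefix}{i:02d}" for i in range(1, spec.n_concepts + 1)]


def _keyword_map(spec: SynthSpec) -> dict[str, list[str]]:
    return {
        cid: [f"kw{i:02d}n{j}" for j in range(spec.keywords_per_concept)]
        for i, cid in enumerate(_concept_ids(spec), start=1)
    }


def split_heldout(
    keyword_map: dict[str, list[str]], fraction: float, seed: int
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Deterministically split each concept's keywords into retained/held-out."""
    rng = np.random.default_rng(seed)
    retained, heldout = {}, {}
    for concept in sorted(keyword_map):
        kws = sorted(keyword_map[concept])
        n_h = int(fraction * len(kws))
        if n_h >= len(kws) and n_h > 0:
            raise ValueError(
                f"holdout {fraction} leaves concept {concept} without training keywords"
            )
        order = rng.permutation(len(kws))
        heldout[concept] = sorted(kws[i] for i in order[:n_h])
        retained[concept] = sorted(kws[i] for i in order[n_h:])
    return retained, heldout


def _make_sentence(
    k: int,
    spec: SynthSpec,
    rng: np.random.Generator,
    concept_ids: list[str],
    emission_map: dict[str, list[str]],
) -> Sentence:
    lo, hi = spec.tokens_per_sentence
    n_tok = int(rng.integers(lo, hi + 1))
    tokens = [f"w{int(rng.integers(spec.background_vocab_size)):03d}" for _ in range(n_tok)]

    concepts: list[str] = []
    if rng.random() < spec.concept_probability:
        concepts.append(concept_ids[int(rng.integers(len(concept_ids)))])
        if len(concept_ids) > 1 and rng.random() < spec.second_concept_probability:
            others = [c for c in concept_ids if c != concepts[0]]
            concepts.append(others[int(rng.integers(len(others)))])

    inserts: list[str] = []
    for c in concepts:
        if rng.random() < spec.keyword_emission:
            kws = emission_map[c]
            n_kw = min(1 + int(rng.random() < 0.5), len(kws))
            picks = rng.choice(len(kws), size=n_kw, replace=False)
            inserts.extend(kws[i] for i in picks)

    ne_rate = spec.ne_rate_concept if concepts else spec.ne_rate_background
    ne_count = 0
    if rng.random() < ne_rate:
        ne_count = int(rng.integers(1, 3))
        inserts.extend(f"gene{int(rng.integers(40))}" for _ in range(ne_count))

    n_ins = min(len(inserts), n_tok)
    if n_ins:
        positions = rng.choice(n_tok, size=n_ins, replace=False)
        for pos, tok in zip(positions, inserts[:n_ins]):
            tokens[pos] = tok

    pas = [(tokens[i], "arg", tokens[i + 1]) for i in range(len(tokens) - 1)]
    return Sentence(
        id=f"s{k}",
        text=" ".join(tokens),
        gold_concepts=Counter(concepts),
        pas_units=pas,
        ne_count=ne_count,
    )


def generate_corpus(spec: SynthSpec, out_dir: Path | str | None = None) -> SyntheticCorpus:
    """Generate dev/train/test splits plus the ground-truth keyword map.

    Splits follow abstract-corpus proportions: 1/6 dev, 1/2 train pool,
    1/3 test.  When ``oov_holdout_fraction`` > 0, held-out keywords are
    emitted only in test documents.  With ``out_dir`` set, standoff files
    are written under ``dev/``, ``train/``, ``test/`` next to
    ``concepts.tsv`` and the ``keywords.tsv`` ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    concept_ids = _concept_ids(spec)
    keyword_map = _keyword_map(spec)
    retained, heldout = split_heldout(
        keyword_map, spec.oov_holdout_fraction, spec.seed
    )

    n = spec.n_documents
    n_dev = max(1, round(n / 6))
    n_test = max(1, round(n / 3))
    if n_dev + n_test >= n:
        raise ValueError("n_documents too small for a dev/train/test split")

    lo, hi = spec.sentences_per_document
    docs: list[Document] = []
    for i in range(n):
        in_test = i >= n - n_test
        emission_map = keyword_map if in_test else retained
        n_sent = int(rng.integers(lo, hi + 1))
        sentences = [
            _make_sentence(k, spec, rng, concept_ids, emission_map)
            for k in range(n_sent)
        ]
        docs.append(Document(id=f"d{i:04d}", sentences=sentences))

    concept_set = ConceptSet.from_pairs((c, spec.concept_kind) for c in concept_ids)
    corpus = SyntheticCorpus(
        concept_set=concept_set,
        dev=docs[:n_dev],
        train=docs[n_dev : n - n_test],
        test=docs[n - n_test :],
        keyword_map=keyword_map,
        heldout_map=heldout,
        spec=spec,
    )
    if out_dir is not None:
        _write_corpus(corpus, Path(out_dir))
    return corpus


def _write_corpus(corpus: SyntheticCorpus, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("dev", "train", "test"):
        write_standoff_corpus(
            getattr(corpus, name), out_dir / name, corpus.concept_set
        )
    write_concept_set(corpus.concept_set, out_dir / "concepts.tsv")
    with open(out_dir / "keywords.tsv", "w") as fh:
        for concept in sorted(corpus.keyword_map):
            for kw in corpus.keyword_map[concept]:
                fh.write(f"{concept}\t{kw}\n")


def generate_similarity_provider(
    keyword_map: dict[str, list[str]], holdout: float, seed: int
) -> tuple[TableSimilarityProvider, list[str]]:
    """Similarity resource for the held-out (OOV) keywords.

    Held-out words are highly similar (0.9) to retained keywords of their
    own concept and barely similar (0.05) to keywords of other concepts.
    Uses the same deterministic holdout split as :func:`generate_corpus`
    when given the same seed.
    """
    retained, heldout = split_heldout(keyword_map, holdout, seed)
    pairs: dict[tuple[str, str], float] = {}
    for concept, held in heldout.items():
        for h in held:
            for other_concept, kws in retained.items():
                s = 0.9 if other_concept == concept else 0.05
                for r in kws:
                    pairs[(h, r)] = s
    heldout_words = sorted(w for ws in heldout.values() for w in ws)
    return TableSimilarityProvider(pairs), heldout_words
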