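"""Document/sentence data model, pools, and standoff annotation I/O.

Documents are plain text files with one sentence per line; annotations live
in separate ``.a1``/``.a2`` files that reference character offsets into the
text (the standoff convention used by the BioNLP shared tasks).  Gold
concepts are tracked per sentence as a multiset; predicate-argument
structure (PAS) units come from a tab-separated sidecar file because they
are produced by an external deep parser, not by this package.
"""

from __future__ import annotations

import string
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Concept",
    "ConceptSet",
    "Sentence",
    "Document",
    "PoolState",
    "FeatureUnit",
    "CorpusFormatError",
    "tokenize",
    "extract_ngrams",
    "sentence_features",
    "read_standoff_corpus",
    "write_standoff_corpus",
    "read_concept_set",
    "write_concept_set",
    "update_pools",
    "PARTICIPANT_TYPE",
    "ANCHOR_TYPE",
]

#: Reserved .a1 entity type marking a predicted event-participant mention
#: (a gene/protein name).  Counted into ``Sentence.ne_count``, never a concept.
PARTICIPANT_TYPE = "Protein"

#: Reserved type for text-bound anchors that exist only so relation lines
#: have arguments to point at.  Ignored on read.
ANCHOR_TYPE = "Entity"

_STRIP = string.punctuation


class CorpusFormatError(ValueError):
    """Raised for malformed standoff files or inconsistent annotations."""


def tokenize(text: str) -> list[str]:
    """Whitespace-split, strip surrounding punctuation, lower-case.

    Empty tokens (pure punctuation fields) are dropped.
    """
    out = []
    for field_ in text.split():
        tok = field_.strip(_STRIP).lower()
        if tok:
            out.append(tok)
    return out


@dataclass(frozen=True)
class Concept:
    identifier: str
    kind: str  # "event" | "relation" | "entity"

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("concept identifier must be non-empty")
        if self.kind not in ("event", "relation", "entity"):
            raise ValueError(f"unknown concept kind: {self.kind!r}")


@dataclass(frozen=True)
class ConceptSet:
    """The ontology's tracked concepts (events, relations or entity types)."""

    concepts: tuple[Concept, ...]

    def __post_init__(self) -> None:
        if not self.concepts:
            raise ValueError("concept set must contain at least one concept")
        ids = [c.identifier for c in self.concepts]
        if len(set(ids)) != len(ids):
            raise ValueError("concept identifiers must be unique")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ConceptSet":
        return cls(tuple(Concept(i, k) for i, k in pairs))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.identifier for c in self.concepts)

    def kind(self, identifier: str) -> str:
        for c in self.concepts:
            if c.identifier == identifier:
                return c.kind
        raise KeyError(identifier)

    def __contains__(self, identifier: object) -> bool:
        return any(c.identifier == identifier for c in self.concepts)

    def __len__(self) -> int:
        return len(self.concepts)


@dataclass
class Sentence:
    """One sentence with its gold concept multiset and optional PAS units.

    ``ne_count`` is the number of predicted participant mentions (T in the
    participant-augmentation term of the informativity score).
    """

    id: str
    text: str
    tokens: list[str] = field(default_factory=list)
    gold_concepts: Counter = field(default_factory=Counter)
    pas_units: list[tuple[str, str, str]] = field(default_factory=list)
    ne_count: int = 0

    def __post_init__(self) -> None:
        if not self.tokens and self.text:
            self.tokens = tokenize(self.text)
        if self.ne_count < 0:
            raise ValueError("ne_count must be >= 0")

    @property
    def word_count(self) -> int:
        return len(self.tokens)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sentence):
            return NotImplemented
        return (
            self.id == other.id
            and self.text == other.text
            and self.tokens == other.tokens
            and self.gold_concepts == other.gold_concepts
            and sorted(self.pas_units) == sorted(other.pas_units)
            and self.ne_count == other.ne_count
        )


@dataclass
class Document:
    id: str
    sentences: list[Sentence]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sentences]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sentence ids in document {self.id}")

    @property
    def size(self) -> int:
        return len(self.sentences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Document):
            return NotImplemented
        return self.id == other.id and self.sentences == other.sentences

    def __hash__(self) -> int:
        return hash(self.id)


@dataclass(frozen=True)
class FeatureUnit:
    """An n-gram (token tuple) or a PAS triple used as a sentence feature."""

    kind: str  # "ngram" | "pas"
    value: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("ngram", "pas"):
            raise ValueError(f"unknown feature kind: {self.kind!r}")
        if not self.value or any(not v for v in self.value):
            raise ValueError("feature value components must be non-empty")
        if self.kind == "pas" and len(self.value) != 3:
            raise ValueError("pas features are (predicate, relation, argument)")


@dataclass(frozen=True)
class PoolState:
    """Labeled / unlabeled document pools at round ``round``."""

    labeled: tuple[Document, ...]
    unlabeled: tuple[Document, ...]
    round: int = 0

    def __post_init__(self) -> None:
        lab = {d.id for d in self.labeled}
        unl = {d.id for d in self.unlabeled}
        if lab & unl:
            raise ValueError(f"pools overlap: {sorted(lab & unl)}")
        if self.round < 0:
            raise ValueError("round must be >= 0")

    @property
    def total(self) -> int:
        return len(self.labeled) + len(self.unlabeled)


def update_pools(state: PoolState, selected: Sequence[Document]) -> PoolState:
    """Move ``selected`` from the unlabeled to the labeled pool; round += 1."""
    unl_ids = {d.id for d in state.unlabeled}
    for d in selected:
        if d.id not in unl_ids:
            raise ValueError(f"document {d.id} is not in the unlabeled pool")
    sel_ids = {d.id for d in selected}
    return PoolState(
        labeled=state.labeled + tuple(selected),
        unlabeled=tuple(d for d in state.unlabeled if d.id not in sel_ids),
        round=state.round + 1,
    )


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_ngrams(sentence: Sentence, order: int | Iterable[int]) -> Counter:
    """Contiguous token n-grams of the given order(s), multiplicity preserved.

    ``order`` may be a single integer or a collection (e.g. ``{1, 2}`` for a
    unigram+bigram mixture).  Order 2 alone yields bigrams only.
    """
    orders = sorted({order} if isinstance(order, int) else set(order))
    if not orders or orders[0] < 1:
        raise ValueError("n-gram order must be >= 1")
    toks = sentence.tokens
    out: Counter = Counter()
    for n in orders:
        for i in range(len(toks) - n + 1):
            out[FeatureUnit("ngram", tuple(toks[i : i + n]))] += 1
    return out


def sentence_features(
    sentence: Sentence, kind: str, ngram_order: int | Iterable[int] = 1
) -> Counter:
    """Feature multiset of one sentence for the requested feature kind."""
    if kind == "ngram":
        return extract_ngrams(sentence, ngram_order)
    if kind == "pas":
        return Counter(FeatureUnit("pas", tuple(u)) for u in sentence.pas_units)
    raise ValueError(f"unknown feature kind: {kind!r}")


# ---------------------------------------------------------------------------
# Standoff I/O
# ---------------------------------------------------------------------------

def _sentence_offsets(lines: list[str]) -> list[int]:
    starts, pos = [], 0
    for ln in lines:
        starts.append(pos)
        pos += len(ln) + 1  # newline
    return starts


def _field_spans(line: str, start: int) -> list[tuple[int, int, str]]:
    """Character spans of whitespace-separated fields, absolute offsets."""
    spans, i = [], 0
    while i < len(line):
        if line[i].isspace():
            i += 1
            continue
        j = i
        while j < len(line) and not line[j].isspace():
            j += 1
        spans.append((start + i, start + j, line[i:j]))
        i = j
    return spans


def write_standoff_corpus(
    documents: Sequence[Document],
    directory: Path | str,
    concept_set: ConceptSet | None = None,
) -> None:
    """Write documents in the standoff dialect read by :func:`read_standoff_corpus`.

    Per document: ``<id>.txt`` (one sentence per line), ``<id>.a1`` (entity
    concepts and participant mentions), ``<id>.a2`` (event triggers+events,
    relation anchors+relations) and, when any sentence has PAS units,
    ``<id>.pas``.  ``concept_set`` supplies the kind of each gold concept;
    without it every concept is serialized as an event.
    """
    kinds = (
        {c.identifier: c.kind for c in concept_set.concepts} if concept_set else {}
    )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in documents:
        lines = [s.text for s in doc.sentences]
        starts = _sentence_offsets(lines)
        a1, a2, pas = [], [], []
        tn = en = rn = 0

        def tline(bucket: list, type_: str, span: tuple[int, int, str]) -> str:
            nonlocal tn
            tn += 1
            tid = f"T{tn}"
            bucket.append(f"{tid}\t{type_} {span[0]} {span[1]}\t{span[2]}")
            return tid

        for k, sent in enumerate(doc.sentences):
            spans = _field_spans(lines[k], starts[k])
            if not spans:  # annotations need a text anchor
                if sent.gold_concepts or sent.ne_count:
                    raise CorpusFormatError(
                        f"{doc.id}/{sent.id}: cannot anchor annotations on empty text"
                    )
                continue
            for i in range(sent.ne_count):
                tline(a1, PARTICIPANT_TYPE, spans[i % len(spans)])
            for concept, mult in sorted(sent.gold_concepts.items()):
                for _ in range(mult):
                    kind = kinds.get(concept, "event")
                    if kind == "entity":
                        tline(a1, concept, spans[0])
                    elif kind == "relation":
                        x = tline(a2, ANCHOR_TYPE, spans[0])
                        y = tline(a2, ANCHOR_TYPE, spans[-1])
                        rn += 1
                        a2.append(f"R{rn}\t{concept} Arg1:{x} Arg2:{y}")
                    else:
                        trig = tline(a2, concept, spans[0])
                        en += 1
                        a2.append(f"E{en}\t{concept}:{trig}")
            for unit in sent.pas_units:
                pas.append(f"{k}\t" + "\t".join(unit))

        (directory / f"{doc.id}.txt").write_text("\n".join(lines) + "\n")
        (directory / f"{doc.id}.a1").write_text("".join(l + "\n" for l in a1))
        (directory / f"{doc.id}.a2").write_text("".join(l + "\n" for l in a2))
        if pas:
            (directory / f"{doc.id}.pas").write_text("".join(l + "\n" for l in pas))


def read_standoff_corpus(directory: Path | str, concept_set: ConceptSet) -> list[Document]:
    """Read all ``<id>.txt`` documents (plus annotations) from a directory.

    Every annotation is assigned to the sentence containing the start offset
    of its trigger (events), first argument (relations) or its own span
    (entities).  Unknown annotation types raise; ``*`` equivalence lines and
    ``#`` comments are ignored.
    """
    directory = Path(directory)
    docs = []
    for txt in sorted(directory.glob("*.txt")):
        docs.append(_read_document(txt, concept_set))
    return docs


def _read_document(txt_path: Path, concept_set: ConceptSet) -> Document:
    docid = txt_path.stem
    raw = txt_path.read_text()
    lines = raw.split("\n")
    if lines and lines[-1] == "":
        lines = lines[:-1]
    starts = _sentence_offsets(lines)
    text_len = len(raw)
    sentences = [Sentence(id=f"s{k}", text=ln) for k, ln in enumerate(lines)]

    def sent_at(offset: int, where: str) -> Sentence:
        if offset < 0 or offset > text_len:
            raise CorpusFormatError(f"{where}: offset {offset} outside text")
        return sentences[bisect_right(starts, offset) - 1]

    tspans: dict[str, tuple[str, int, int]] = {}
    for suffix in (".a1", ".a2"):
        path = txt_path.with_suffix(suffix)
        if not path.exists():
            continue
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#") or line.startswith("*"):
                continue
            where = f"{path.name}:{lineno}"
            try:
                _parse_standoff_line(line, where, concept_set, tspans, sent_at)
            except CorpusFormatError:
                raise
            except Exception as exc:  # malformed field counts, bad ints, ...
                raise CorpusFormatError(f"{where}: malformed line ({exc})") from exc

    pas_path = txt_path.with_suffix(".pas")
    if pas_path.exists():
        for lineno, line in enumerate(pas_path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CorpusFormatError(
                    f"{pas_path.name}:{lineno}: expected 4 tab-separated fields"
                )
            idx = int(parts[0])
            if not 0 <= idx < len(sentences):
                raise CorpusFormatError(
                    f"{pas_path.name}:{lineno}: sentence index {idx} out of range"
                )
            sentences[idx].pas_units.append((parts[1], parts[2], parts[3]))

    return Document(id=docid, sentences=sentences)


def _parse_standoff_line(line, where, concept_set, tspans, sent_at) -> None:
    tag, rest = line.split("\t", 1)
    if tag.startswith("T"):
        ann, _surface = rest.split("\t", 1)
        type_, s, e = ann.split(" ")
        start, end = int(s), int(e)
        if start > end:
            raise CorpusFormatError(f"{where}: start > end")
        sent = sent_at(start, where)
        sent_at(end, where)
        tspans[tag] = (type_, start, end)
        if type_ == PARTICIPANT_TYPE:
            sent.ne_count += 1
        elif type_ == ANCHOR_TYPE:
            pass  # relation argument anchor only
        elif type_ in concept_set:
            if concept_set.kind(type_) == "entity":
                sent.gold_concepts[type_] += 1
            # event trigger: the E line carries the gold concept
        else:
            raise CorpusFormatError(f"{where}: unknown concept identifier {type_!r}")
    elif tag.startswith("E"):
        args = rest.split(" ")
        type_, trig = args[0].split(":")
        if type_ not in concept_set:
            raise CorpusFormatError(f"{where}: unknown concept identifier {type_!r}")
        if trig not in tspans:
            raise CorpusFormatError(f"{where}: undefined trigger {trig!r}")
        sent = sent_at(tspans[trig][1], where)
        sent.gold_concepts[type_] += 1
    elif tag.startswith("R"):
        parts = rest.split(" ")
        type_ = parts[0]
        if type_ not in concept_set:
            raise CorpusFormatError(f"{where}: unknown concept identifier {type_!r}")
        arg1 = parts[1].split(":")[1]
        if arg1 not in tspans:
            raise CorpusFormatError(f"{where}: undefined argument {arg1!r}")
        sent = sent_at(tspans[arg1][1], where)
        sent.gold_concepts[type_] += 1
    else:
        raise CorpusFormatError(f"{where}: unrecognized annotation tag {tag!r}")


def write_concept_set(concept_set: ConceptSet, path: Path | str) -> None:
    Path(path).write_text(
        "".join(f"{c.identifier}\t{c.kind}\n" for c in concept_set.concepts)
    )


def read_concept_set(path: Path | str) -> ConceptSet:
    pairs = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            ident, kind = line.split("\t")
            pairs.append((ident, kind))
    return ConceptSet.from_pairs(pairs)
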