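"""The iterative active-learning protocol.

Initialization trains the base recognizer and the statistical models on the
development split only.  Each round ranks the unlabeled pool with the
configured strategy under the round's models, moves the top-b documents
(with their gold annotations, simulating manual annotation) into the
labeled pool, refits everything from the enlarged pool, and evaluates the
recognizer on the fixed test split.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .corpus import ConceptSet, Document, PoolState, update_pools
from .evaluation import LearningCurve, recognition_f1
from .informativity import (
    InformativityConfig,
    InformativityScorer,
    PriorModel,
    SimilarityProvider,
    fit_prior,
)
from .learner import MockKeywordLearner, RecognizerContract
from .stats import CorrelationModel, fit_correlation_model
from .strategies import (
    committee_disagreement,
    entropy_document_score,
    gibbs_document_score,
    rank_by_score,
    rank_informativity,
    random_ranking,
)

__all__ = ["LoopConfig", "LoopState", "initialize", "run_round", "run", "STRATEGIES"]

STRATEGIES = ("informativity", "committee", "entropy", "gibbs", "random")


@dataclass(frozen=True)
class LoopConfig:
    """Protocol parameters: batch fraction b, number of rounds, strategy.

    Defaults follow the standard design: 10 rounds, each adding 10% of the
    original unlabeled pool.  ``task="ner"`` restricts features to n-grams
    (PAS features carry no signal for entity mentions).
    """

    batch_fraction: float = 0.1
    rounds: int = 10
    strategy: str = "informativity"
    seed: int = 0
    task: str = "event"  # "event" | "ner"
    learner_threshold: int = 6
    inform: InformativityConfig = field(default_factory=InformativityConfig)

    def __post_init__(self) -> None:
        if not 0 < self.batch_fraction <= 1:
            raise ValueError("batch_fraction must be in (0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.task not in ("event", "ner"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "ner" and (
            self.inform.beta > 0 or self.inform.feature_kind == "pas"
        ):
            raise ValueError("NER mode uses n-gram features only (beta must be 0)")


@dataclass
class LoopState:
    """Pools plus the models fitted from the current labeled pool."""

    pools: PoolState
    learner: RecognizerContract
    prior: PriorModel
    ngram_model: CorrelationModel | None
    pas_model: CorrelationModel | None
    selection_log: list[list[str]] = field(default_factory=list)
    round_seconds: list[float] = field(default_factory=list)


def _fit_models(
    labeled: Sequence[Document],
    concept_set: ConceptSet,
    config: LoopConfig,
    learner: RecognizerContract,
) -> tuple[PriorModel, CorrelationModel | None, CorrelationModel | None]:
    sentences = [s for d in labeled for s in d.sentences]
    learner.train(labeled, concept_set)
    prior = fit_prior(sentences, concept_set)
    inform = config.inform
    need_ngram = config.strategy in ("entropy", "gibbs", "committee") or (
        config.strategy == "informativity" and inform.alpha > 0
    )
    need_pas = config.strategy == "informativity" and inform.beta > 0
    ngram_model = (
        fit_correlation_model(
            sentences,
            concept_set,
            method=inform.method,
            feature_kind="ngram",
            ngram_order=inform.ngram_order,
        )
        if need_ngram
        else None
    )
    pas_model = (
        fit_correlation_model(
            sentences, concept_set, method=inform.method, feature_kind="pas"
        )
        if need_pas
        else None
    )
    return prior, ngram_model, pas_model


def initialize(
    dev_documents: Sequence[Document],
    unlabeled_pool: Sequence[Document],
    concept_set: ConceptSet,
    config: LoopConfig,
    learner: RecognizerContract | None = None,
) -> LoopState:
    """Round-0 state: everything fitted from the development split."""
    if not dev_documents:
        raise ValueError("development set must be non-empty")
    if learner is None:
        learner = MockKeywordLearner(threshold=config.learner_threshold)
    prior, ngram_model, pas_model = _fit_models(
        dev_documents, concept_set, config, learner
    )
    pools = PoolState(
        labeled=tuple(dev_documents), unlabeled=tuple(unlabeled_pool), round=0
    )
    return LoopState(
        pools=pools,
        learner=learner,
        prior=prior,
        ngram_model=ngram_model,
        pas_model=pas_model,
    )


def _rank(
    state: LoopState,
    concept_set: ConceptSet,
    config: LoopConfig,
    sim: SimilarityProvider | None,
) -> list[Document]:
    docs = state.pools.unlabeled
    if config.strategy == "informativity":
        scorer = InformativityScorer(
            concept_set=concept_set,
            config=config.inform,
            learner=state.learner,
            prior=state.prior,
            ngram_model=state.ngram_model,
            pas_model=state.pas_model,
            sim=sim,
        )
        return rank_informativity(docs, scorer)
    if config.strategy == "committee":
        return rank_by_score(
            docs,
            lambda d: committee_disagreement(
                d, concept_set, state.learner, state.prior, state.ngram_model
            ),
        )
    if config.strategy == "entropy":
        return rank_by_score(
            docs,
            lambda d: entropy_document_score(
                d, concept_set, state.ngram_model, state.prior
            ),
        )
    if config.strategy == "gibbs":
        return rank_by_score(
            docs,
            lambda d: gibbs_document_score(
                d, concept_set, state.ngram_model, state.prior
            ),
        )
    # random: per-round seed derived deterministically from the run seed
    round_seed = (config.seed * 100003 + state.pools.round + 1) % (2**31 - 1)
    return random_ranking(docs, round_seed)


def run_round(
    state: LoopState,
    concept_set: ConceptSet,
    config: LoopConfig,
    batch_size: int,
    sim: SimilarityProvider | None = None,
) -> LoopState:
    """One selection round: rank, select top-b, update pools, refit."""
    if not state.pools.unlabeled:
        raise RuntimeError("unlabeled pool is empty")
    start = time.perf_counter()
    ranked = _rank(state, concept_set, config, sim)
    batch = ranked[: min(batch_size, len(ranked))]
    pools = update_pools(state.pools, batch)
    prior, ngram_model, pas_model = _fit_models(
        pools.labeled, concept_set, config, state.learner
    )
    return LoopState(
        pools=pools,
        learner=state.learner,
        prior=prior,
        ngram_model=ngram_model,
        pas_model=pas_model,
        selection_log=state.selection_log + [[d.id for d in batch]],
        round_seconds=state.round_seconds + [time.perf_counter() - start],
    )


def run(
    dev: Sequence[Document],
    train_pool: Sequence[Document],
    test: Sequence[Document],
    concept_set: ConceptSet,
    config: LoopConfig,
    eval_hook: Callable[[RecognizerContract, Sequence[Document]], float] | None = None,
    sim: SimilarityProvider | None = None,
) -> tuple[LearningCurve, LoopState]:
    """Full protocol: initialize on dev, iterate rounds, score on fixed test.

    The per-round score defaults to the recognizer's sentence-level micro-F1
    on the test split.  The batch size is ceil(batch_fraction * initial pool
    size), fixed across rounds.
    """
    _check_disjoint(dev, train_pool, test)
    if eval_hook is None:
        eval_hook = lambda lrn, docs: recognition_f1(lrn, docs, concept_set)
    state = initialize(dev, train_pool, concept_set, config)
    batch_size = max(1, math.ceil(config.batch_fraction * len(train_pool)))
    scores, n_labeled = [], []
    for _ in range(config.rounds):
        if not state.pools.unlabeled:
            break
        state = run_round(state, concept_set, config, batch_size, sim=sim)
        scores.append(eval_hook(state.learner, test))
        n_labeled.append(len(state.pools.labeled) - len(dev))
    curve = LearningCurve(
        scores=tuple(scores), n_labeled=tuple(n_labeled), strategy=config.strategy
    )
    return curve, state


def _check_disjoint(*splits: Sequence[Document]) -> None:
    seen: dict[str, int] = {}
    for i, split in enumerate(splits):
        for d in split:
            if d.id in seen:
                raise ValueError(f"document {d.id} appears in two splits")
            seen[d.id] = i
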