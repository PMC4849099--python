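"""Priors, Z scores, posteriors, recognizer filtering, OOV backoff and the
linear combination."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evental import (
    ConceptSet,
    CorrelationModel,
    Document,
    FeatureUnit,
    InformativityConfig,
    InformativityScorer,
    PriorModel,
    TableSimilarityProvider,
    combined_sentence_informativity,
    concept_posteriors,
    document_informativity,
    fit_correlation_model,
    fit_prior,
    ne_informativity,
    oov_weight,
    sentence_informativity,
    sentence_likelihood,
    z_score,
)
from conftest import StubLearner, make_sentence


def hand_model(weights, concepts, log_norm=None):
    """A model with directly chosen weights; log_norm 0 makes p = exp(W)."""
    concepts = tuple(concepts)
    return CorrelationModel(
        method="chi2_yates",
        feature_kind="ngram",
        ngram_order=1,
        weights={(FeatureUnit("ngram", (tok,)), c): w for (tok, c), w in weights.items()},
        concepts=concepts,
        log_norm=log_norm or {c: 0.0 for c in concepts},
    )


class TestPrior:
    def test_mle_fractions(self, two_concepts):
        sents = [make_sentence(f"s{i}", ["x"], gold=["E1"]) for i in range(3)]
        sents.append(make_sentence("s3", ["x"], gold=["E2"]))
        prior = fit_prior(sents, two_concepts)
        assert prior["E1"] == pytest.approx(0.75)
        assert prior["E2"] == pytest.approx(0.25)

    def test_single_concept_gets_everything(self):
        cs = ConceptSet.from_pairs([("E1", "event")])
        prior = fit_prior([make_sentence("s0", ["x"], gold=["E1"])], cs)
        assert prior["E1"] == pytest.approx(1.0)

    def test_unseen_concept_gets_floor(self, two_concepts):
        sents = [make_sentence(f"s{i}", ["x"], gold=["E1"]) for i in range(4)]
        prior = fit_prior(sents, two_concepts)
        assert prior["E2"] == pytest.approx(1e-6 / (4 + 1e-6))
        assert prior["E2"] > 0

    def test_no_annotations_is_an_error(self, two_concepts):
        with pytest.raises(RuntimeError):
            fit_prior([make_sentence("s0", ["x"])], two_concepts)


class TestZScore:
    def test_length_normalized_sum(self):
        m = hand_model({("a", "E1"): math.log(0.2), ("b", "E1"): math.log(0.4)}, ["E1"])
        s = make_sentence("s0", ["a", "b"])
        assert z_score(s, "E1", m) == pytest.approx(0.3)

    def test_all_oov_scores_zero(self):
        m = hand_model({("a", "E1"): 0.0}, ["E1"])
        assert z_score(make_sentence("s0", ["q", "r"]), "E1", m) == 0.0

    def test_occurrences_counted(self):
        m = hand_model({("a", "E1"): math.log(0.2)}, ["E1"])
        s = make_sentence("s0", ["a", "a"])
        assert z_score(s, "E1", m) == pytest.approx(0.2)

    def test_empty_sentence_scores_zero(self):
        m = hand_model({("a", "E1"): 0.0}, ["E1"])
        assert z_score(make_sentence("s0", []), "E1", m) == 0.0


class TestLikelihoodAndPosterior:
    def test_uniform_when_z_equal(self, two_concepts):
        m = hand_model(
            {("a", "E1"): math.log(0.5), ("a", "E2"): math.log(0.5)},
            two_concepts.ids,
        )
        lik = sentence_likelihood(make_sentence("s0", ["a"]), two_concepts, m)
        assert lik["E1"] == pytest.approx(0.5)

    def test_closed_form_quarter_three_quarters(self, two_concepts):
        # Z = 0 vs ln 3 gives softmax (0.25, 0.75)
        m = hand_model({("a", "E2"): math.log(math.log(3))}, two_concepts.ids)
        s = make_sentence("s0", ["a"])
        assert z_score(s, "E2", m) == pytest.approx(math.log(3))
        lik = sentence_likelihood(s, two_concepts, m)
        assert lik["E1"] == pytest.approx(0.25)
        assert lik["E2"] == pytest.approx(0.75)

    def test_posterior_is_elementwise_product(self, two_concepts):
        # likelihoods (0.3, 0.7) via Z = (0, ln(7/3)); priors (0.6, 0.4)
        m = hand_model({("a", "E2"): math.log(math.log(7 / 3))}, two_concepts.ids)
        prior = PriorModel({"E1": 0.6, "E2": 0.4})
        post = concept_posteriors(make_sentence("s0", ["a"]), two_concepts, prior, m)
        assert post["E1"] == pytest.approx(0.6 * 0.3)
        assert post["E2"] == pytest.approx(0.4 * 0.7)

    def test_zero_prior_zero_posterior(self, two_concepts):
        m = hand_model({("a", "E1"): 0.0, ("a", "E2"): 0.0}, two_concepts.ids)
        prior = PriorModel({"E1": 0.0, "E2": 1.0})
        post = concept_posteriors(make_sentence("s0", ["a"]), two_concepts, prior, m)
        assert post["E1"] == 0.0


class TestFiltering:
    def _setup(self, two_concepts):
        m = hand_model({("a", "E2"): math.log(math.log(7 / 3))}, two_concepts.ids)
        prior = PriorModel({"E1": 0.6, "E2": 0.4})
        return make_sentence("s0", ["a"]), prior, m

    def test_all_recognized_scores_zero(self, two_concepts):
        s, prior, m = self._setup(two_concepts)
        learner = StubLearner(recognized={("s0", "E1"), ("s0", "E2")})
        assert sentence_informativity(s, two_concepts, learner, prior, m) == 0.0

    def test_none_recognized_sums_posteriors(self, two_concepts):
        s, prior, m = self._setup(two_concepts)
        got = sentence_informativity(s, two_concepts, StubLearner(), prior, m)
        assert got == pytest.approx(0.18 + 0.28)

    def test_partial_filtering(self, two_concepts):
        s, prior, m = self._setup(two_concepts)
        learner = StubLearner(recognized={("s0", "E1")})
        got = sentence_informativity(s, two_concepts, learner, prior, m)
        assert got == pytest.approx(0.28)

    def test_filtering_dominance(self, two_concepts):
        s, prior, m = self._setup(two_concepts)
        full = sentence_informativity(s, two_concepts, StubLearner(), prior, m)
        for rec in ({("s0", "E1")}, {("s0", "E2")}, {("s0", "E1"), ("s0", "E2")}):
            filtered = sentence_informativity(
                s, two_concepts, StubLearner(recognized=rec), prior, m
            )
            assert filtered <= full


class TestParticipantTerm:
    @pytest.mark.parametrize("t,delta,expected", [(0, 0.25, 0.0), (2, 0.25, 0.5)])
    def test_delta_times_count(self, t, delta, expected):
        s = make_sentence("s0", ["x"], ne_count=t)
        assert ne_informativity(s, delta) == pytest.approx(expected)

    def test_default_delta_is_quarter(self):
        assert InformativityConfig().delta == 0.25

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            ne_informativity(make_sentence("s0", ["x"]), -0.1)


class TestOOV:
    def _model(self):
        return hand_model(
            {("in1", "E1"): 0.2, ("in2", "E1"): 0.4, ("in1", "E2"): 0.0, ("in2", "E2"): 0.0},
            ["E1", "E2"],
        )

    def test_weighted_neighbor_sum(self):
        sim = TableSimilarityProvider({("out", "in1"): 0.5, ("out", "in2"): 0.5})
        got = oov_weight("out", "E1", self._model(), sim, k=2)
        assert got == pytest.approx(0.2 * 0.5 + 0.4 * 0.5)

    def test_no_neighbors_gives_zero(self):
        sim = TableSimilarityProvider({})
        assert oov_weight("out", "E1", self._model(), sim, k=5) == 0.0

    def test_k_limits_neighbors(self):
        sim = TableSimilarityProvider({("out", "in1"): 0.9, ("out", "in2"): 0.5})
        got = oov_weight("out", "E1", self._model(), sim, k=1)
        assert got == pytest.approx(0.2 * 0.9)  # in1 is the closer neighbor

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            oov_weight("out", "E1", self._model(), TableSimilarityProvider({}), k=0)

    def test_identical_neighbors_scale_linearly(self):
        # k neighbors with equal W and equal Sim give exactly k * w * s
        w, s_val, k = 0.3, 0.6, 4
        weights = {(f"in{i}", "E1"): w for i in range(k)}
        m = hand_model(weights, ["E1"])
        sim = TableSimilarityProvider({("out", f"in{i}"): s_val for i in range(k)})
        assert oov_weight("out", "E1", m, sim, k=k) == pytest.approx(k * w * s_val)

    def test_default_k_is_25(self):
        assert InformativityConfig().k == 25


class TestCombination:
    def _fixtures(self, two_concepts):
        m = hand_model({("a", "E2"): math.log(math.log(7 / 3))}, two_concepts.ids)
        prior = PriorModel({"E1": 0.6, "E2": 0.4})
        s = make_sentence("s0", ["a"], ne_count=2)
        return s, prior, m

    def test_gamma_only_equals_participant_term(self, two_concepts):
        s, prior, m = self._fixtures(two_concepts)
        cfg = InformativityConfig(alpha=0, beta=0, gamma=1)
        got = combined_sentence_informativity(
            s, two_concepts, cfg, StubLearner(), prior, ngram_model=m
        )
        assert got == pytest.approx(ne_informativity(s, cfg.delta))

    def test_alpha_only_equals_ngram_informativity(self, two_concepts):
        s, prior, m = self._fixtures(two_concepts)
        cfg = InformativityConfig(alpha=1, beta=0, gamma=0)
        got = combined_sentence_informativity(
            s, two_concepts, cfg, StubLearner(), prior, ngram_model=m
        )
        assert got == pytest.approx(
            sentence_informativity(s, two_concepts, StubLearner(), prior, m)
        )

    def test_weighted_sum_of_components(self, two_concepts):
        s, prior, m = self._fixtures(two_concepts)
        cfg = InformativityConfig(alpha=0.1, beta=0.0, gamma=0.8)
        ng = sentence_informativity(s, two_concepts, StubLearner(), prior, m)
        ne = ne_informativity(s, cfg.delta)
        got = combined_sentence_informativity(
            s, two_concepts, cfg, StubLearner(), prior, ngram_model=m
        )
        assert got == pytest.approx(0.1 * ng + 0.8 * ne)

    def test_missing_model_for_nonzero_weight_fails(self, two_concepts):
        s, prior, m = self._fixtures(two_concepts)
        cfg = InformativityConfig(alpha=0.5, beta=0.5, gamma=0)
        with pytest.raises(RuntimeError):
            combined_sentence_informativity(
                s, two_concepts, cfg, StubLearner(), prior, ngram_model=m
            )

    def test_monotone_in_ne_count(self, two_concepts):
        _, prior, m = self._fixtures(two_concepts)
        cfg = InformativityConfig(alpha=0.1, beta=0.0, gamma=0.8)
        scores = [
            combined_sentence_informativity(
                make_sentence("s0", ["a"], ne_count=t),
                two_concepts,
                cfg,
                StubLearner(),
                prior,
                ngram_model=m,
            )
            for t in range(4)
        ]
        assert all(x < y for x, y in zip(scores, scores[1:]))


class TestDocumentScore:
    def test_mean_over_sentences(self):
        doc = Document(
            id="d1",
            sentences=[make_sentence("s0", ["x"]), make_sentence("s1", ["y"])],
        )
        scores = {"s0": 0.2, "s1": 0.4}
        assert document_informativity(doc, lambda s: scores[s.id]) == pytest.approx(0.3)

    def test_single_sentence_is_identity(self):
        doc = Document(id="d1", sentences=[make_sentence("s0", ["x"])])
        assert document_informativity(doc, lambda s: 0.7) == pytest.approx(0.7)

    def test_empty_document_is_an_error(self):
        with pytest.raises(ValueError):
            document_informativity(Document(id="d1", sentences=[]), lambda s: 0.0)


class TestPlantedKeywordRecovery:
    def test_top_weights_recover_planted_vocabulary(self, small_corpus):
        sents = [s for d in small_corpus.all_documents for s in d.sentences]
        model = fit_correlation_model(sents, small_corpus.concept_set)
        for cid, kws in small_corpus.keyword_map.items():
            ranked = sorted(
                ((w, f) for (f, c), w in model.weights.items() if c == cid),
                key=lambda t: (-t[0], t[1].value),
            )
            top = {f.value[0] for _, f in ranked[: len(kws)]}
            assert len(top & set(kws)) / len(kws) >= 0.9
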