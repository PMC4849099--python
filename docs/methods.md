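# Methods

This note records how the selection framework is modeled, the parameter
choices that matter, what the synthetic benchmark does and does not show,
and the numerical decisions a maintainer should know about.

## The selection protocol

Documents live in two pools: labeled 𝓛 and unlabeled 𝓤. Round 0 trains the
base recognizer and the statistical models on the development split only
(𝓛⁽⁰⁾ = dev). Each round ranks 𝓤 under the current models, moves the top
*b* documents with their gold annotations into 𝓛 (simulated annotation),
refits everything from scratch on the enlarged 𝓛, and evaluates the
recognizer on a fixed test split. The batch size is
⌈batch_fraction × |initial pool|⌉ — a fraction of the *original* pool, so
ten rounds at 10 % exhaust it exactly. Models are refit from scratch each
round rather than updated incrementally; at the corpus sizes involved a
refit costs well under a second and avoids any path dependence.

## The informativity estimator

Per sentence and concept, the score is the unnormalized Bayes product
p(E)·p(S|E), zeroed for concepts the recognizer already extracts from that
sentence. Two modeling points deserve emphasis:

- **The sentence evidence p(S) is treated as the constant 1.** Normalizing
  the posterior per sentence would force Σ_i p(E_i|S) = 1 for every
  sentence, so all fully-unrecognized sentences would score identically and
  the ranking would collapse. The scores are only ever compared, never
  interpreted as calibrated probabilities.
- **The per-concept prior uses an ε = 10⁻⁶ count floor** so that a concept
  absent from the labeled pool keeps a positive posterior and can still
  attract selection.

The likelihood p(S|E) is a softmax over the concept set of Z(S:E), where Z
averages p(feature|E) over the sentence's feature occurrences and divides
by the token count. p(feature|E) is itself a softmax of the association
weight W over the training vocabulary, computed once per concept with a
log-sum-exp normalizer.

A consequence worth knowing: chi-square weights grow with the corpus (a
perfectly correlated keyword in N sentences has W of order N), so the
vocabulary softmax is nearly winner-take-all and the resulting likelihood
tilt between concepts is small. The estimator still ranks correctly — the
planted-keyword and OOV checks pass with margin — but in a closed loop the
*filter* (recognized concepts contribute zero) dominates the *likelihood*
term. Pure n-gram informativity therefore prefers documents in which the
recognizer finds little, which on a synthetic corpus without recognizer
errors includes genuinely empty documents. The participant term (γ > 0)
supplies the complementary density signal, which is why the tuned
combination weights put most mass there; the same behavior motivated the
participant term in the original design.

### Association measures

2×2 tables count *sentences* (presence, not multiplicity, on both axes: a
feature occurring twice in a sentence counts once, as does a concept
annotated twice). Three measures are available:

- **Yates chi-square** (default): N·(|ad−bc| − N/2)² / (N_S·N_F·N_A·N_B),
  implemented exactly in this form. The correction term is squared even
  when |ad−bc| < N/2; a `clamp` flag provides the textbook variant that
  floors the corrected difference at zero. Tables with a zero marginal are
  degenerate; during model fitting they contribute W = 0 (the standalone
  function raises).
- **Relative risk** and **odds ratio**, with the Haldane–Anscombe +0.5
  continuity correction applied to all four cells only when some cell is
  zero, keeping the scores finite.

Chi-square is undirected (strong *negative* association also scores high);
with the generator's disjoint keyword vocabularies this does not arise, but
it is a known property of the measure as specified.

### Parameters

| parameter | default | meaning |
|---|---|---|
| δ | 0.25 | weight per predicted participant mention (dimensionless) |
| (α, β, γ) | (0.1, 0.1, 0.8) | combination weights: n-gram, PAS, participant terms |
| k | 25 | OOV similarity neighbors |
| n-gram order | 1 | unigrams; order 2 means bigrams only, {1,2} mixes |
| batch_fraction | 0.1 | per-round batch as a fraction of the initial pool |
| rounds | 10 | selection rounds |

δ, k and (α, β, γ) are the tuned operating points of the original method
and are exposed in `InformativityConfig`. OOV backoff applies to unigrams
only (word similarity resources are word-level); unknown higher-order
features score zero. In NER mode the concept set contains entity types,
PAS features are rejected by validation, and the combination defaults to
(0.1, 0, 0.8).

### Uncertainty baselines

The entropy and Gibbs-error strategies need p(E_i | NG_j) at each n-gram.
The fitted model provides p(NG_j | E_i); the node posterior is obtained by
Bayes over the concept set, p(E_i|NG_j) ∝ p(E_i)·p(NG_j|E_i), using the
MLE prior. Entropy uses the binary entropy of that probability in bits
(base 2); Gibbs uses 1 − p². Out-of-vocabulary n-grams are skipped in both
(they carry no fitted probability); both scores are sums over sentences of
length-normalized sums over n-gram occurrences.

The committee strategy compares the informativity posterior (computed for
*all* sentences, without the recognized-concept filter) with the
recognizer's distribution: its own per-concept probabilities when it
exposes them (a CRF's marginals would), otherwise a softmax over concepts
of the difference-2 margin (best decision value minus runner-up). The
margin as printed is a property of the whole sentence, not of a concept, so
the fallback distribution is uniform — the disagreement then measures how
far the statistical posterior departs from uniform.

## The mock recognizer

The closed loop needs a base learner whose quality genuinely improves with
more labels. The mock recognizer counts, per concept, how many labeled
sentences pair each token with that concept; it recognizes a concept in a
new sentence when some token reached a count threshold during training.
The threshold is the one free operating point: it must exceed the chance
co-occurrence count that a background token accumulates with any single
concept over the full pool (about 1 under the default generator), or the
recognizer saturates and its precision collapses as labels accumulate. The
default of 6 keeps the learning curve monotone over the benchmark horizon
while leaving enough headroom in early rounds for selection strategies to
differ. Decision values are (max token count − threshold); calibrated
probabilities are an opt-in (softmax of decision values) so both committee
code paths can be exercised.

## The synthetic benchmark

The generator emulates the statistical structure the method exploits — and
only that:

- 10 concepts, each owning 5 unique keyword tokens; 500 background tokens;
  200 documents of 3–8 sentences of 6–12 tokens (dev/train/test split
  1/6 : 1/2 : 1/3, abstract-corpus proportions).
- A sentence expresses a concept with probability 0.6 and a second distinct
  concept with probability 0.25 given the first, exercising the multi-label
  setting; each expressed concept plants 1–2 of its keywords with
  probability 0.9.
- Entity mentions are planted at rate 0.4 in concept-bearing sentences and
  0.05 otherwise (1–2 mentions), so participant density correlates with
  annotation density as it does in event corpora.
- PAS units are proxied by adjacent-token (head, "arg", dependent) pairs —
  enough to exercise the PAS code path, with no syntactic content.
- An optional holdout fraction removes keywords from dev/train emission so
  they appear only in test documents as genuine OOV words; the paired
  similarity provider scores them 0.9 against retained same-concept
  keywords and 0.05 across concepts.

Uniform (non-Zipfian) token frequencies, disjoint trigger vocabularies and
an error-free oracle annotator are deliberate simplifications. Passing the
closed-loop checks here shows the machinery is correct and that the
selection signal behaves as designed under its own assumptions; it does not
predict deficiency magnitudes on real corpora, where trigger ambiguity,
recognizer errors and document-length variation all matter.

## Numerical choices and degenerate inputs

- Softmax everywhere is computed shift-invariantly (max subtraction or
  log-sum-exp); outputs normalize to 1 within 10⁻¹².
- Zero-length sentences score 0 instead of raising inside document means;
  empty documents are rejected at ranking time.
- Deterministic tie-breaks throughout: document ranking by (−score, id),
  concept ranking by (−score, identifier), similarity neighbors by
  (−similarity, word). Identical (corpus, config, seed) runs produce
  byte-identical selection logs and curves; the random strategy derives a
  per-round seed from the run seed.
- Deficiency requires equal-length, non-flat reference curves; it is
  invariant under shifting both curves by a constant and scaling both by a
  positive factor.
- Tokenization: whitespace split, surrounding punctuation stripped,
  lower-cased; sentence segmentation is one sentence per text line, which
  keeps standoff offsets exact. Annotations attach to the sentence
  containing their trigger's (events) or first argument's (relations) start
  offset.

## Known limitations

- The framework scores at sentence level; cross-sentence events are
  attributed to the trigger's sentence.
- The standoff dialect is the minimal subset needed here: equivalence (`*`)
  lines are parsed and ignored; normalization and modification layers are
  out of scope, as is running any parser or NER tool.
- Entropy/Gibbs scores depend on the Bayes construction of p(E|NG) above;
  other constructions (e.g. per-feature binary indicators) would change the
  baselines, not the proposed method.
- With chi-square weights the vocabulary softmax saturates (see above);
  relative risk or odds ratio give softer distributions at the cost of the
  measure's ranking quality on small tables.
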