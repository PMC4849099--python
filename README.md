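# evental

Committee-based active learning for ontological event extraction and
named-entity annotation.

Manually annotating biomedical text with ontology concepts — events such as
*GeneRegulation* or *Phosphorylation*, relations, or entity types — is the
main cost in building information-extraction corpora. Pool-based active
learning reduces that cost by ranking the unlabeled documents and sending
only the most useful ones to the annotators. `evental` implements a
selection framework built around a statistical **informativity** estimate:
a document is worth annotating when it likely expresses concepts that the
current base recognizer (an event-extraction or NER system, abstracted
behind a small contract) fails to find.

## The score

For a document *x* with sentences *S*₁…, the selector maximizes

```
I(x) = (1/‖x‖) Σ_k I(S_k)
```

where a sentence's informativity for the concept set ℰ is the sum of the
posterior probabilities of the concepts the recognizer does **not** yet
extract from it:

```
I(S_k, ℰ) = Σ_{E_i ∈ ℰ}  0                     if E_i is recognized in S_k
                         p(E_i) · p(S_k | E_i)  otherwise
```

The prior p(E_i) is the maximum-likelihood estimate from sentence-level
annotation counts. The likelihood is a softmax over concepts of a
correlation score Z(S_k : E_i) — the length-normalized sum of
p(feature | E_i) over the sentence's n-grams (or predicate–argument
triples), where p(feature | E_i) = σ(W(feature, E_i)) is a softmax over the
training vocabulary of a 2×2-table association weight W: Yates'
continuity-corrected chi-square, relative risk, or odds ratio, computed
from sentence counts cross-classifying feature presence and concept
expression.

Three optional refinements: a participant term δ·T rewarding sentences with
T predicted gene/protein mentions (δ = 0.25), similarity-based backoff for
out-of-vocabulary unigrams (sum of W over the top-k = 25 nearest
in-vocabulary neighbors, weighted by similarity), and a linear combination
α·I(n-gram) + β·I(PAS) + γ·(δ·T) with tuned default weights
(α, β, γ) = (0.1, 0.1, 0.8).

Baselines for comparison: two-member committee disagreement (|p_inf −
p_recognizer| summed over concepts and sentences), entropy and Gibbs-error
uncertainty sampling over n-gram label posteriors, and seeded random
selection. Learning curves are summarized with the **deficiency** metric

```
Def_n(AL, REF) = Σ_t (acc_n(REF) − acc_t(AL)) / Σ_t (acc_n(REF) − acc_t(REF))
```

values below 1 mean the strategy beats the (averaged random) reference.

Everything runs end to end without external systems or downloads: a seeded
synthetic-corpus generator plants concept-specific trigger vocabularies in
noisy sentences, and a trainable mock keyword recognizer closes the loop.
Real recognizers plug in behind `RecognizerContract`.

## Worked example

Simulate ten selection rounds (each adding 10 % of the pool) on the default
synthetic benchmark — 200 documents, a 10-concept ontology, 5 planted
trigger keywords per concept — and compare informativity-guided selection
with the 10-seed averaged random baseline:

```python
from evental import (SynthSpec, generate_corpus, LoopConfig, InformativityConfig,
                     run, average_curves, deficiency)

corpus = generate_corpus(SynthSpec(seed=1))   # 200 documents, 10 concepts
inform = InformativityConfig(alpha=0.1, beta=0.1, gamma=0.8)
args = (corpus.dev, corpus.train, corpus.test, corpus.concept_set)

al, _ = run(*args, LoopConfig(strategy="informativity", seed=1, inform=inform))
rs = [run(*args, LoopConfig(strategy="random", seed=s, inform=inform))[0]
      for s in range(10)]
ref = average_curves(rs, "RS_Average")

for t, (a, r) in enumerate(zip(al.scores, ref.scores), start=1):
    print(f"{t:>5}  {a:>13.3f}  {r:>10.3f}")
print(f"deficiency vs RS_Average: {deficiency(al, ref):.3f}")
```

```
round  informativity  RS_Average
    1          0.687       0.658
    2          0.803       0.776
    3          0.875       0.853
    4          0.886       0.905
    5          0.910       0.928
    6          0.939       0.934
   ...
   10          0.939       0.939
deficiency vs RS_Average: 0.914
```

The scores are the mock recognizer's sentence-level micro-F1 on the fixed
test split after each round. The deficiency of 0.914 < 1 says the guided
selection reached the random baseline's final quality faster, mostly by
front-loading documents rich in unrecognized concepts and entity mentions
(the early-round gap, e.g. 0.687 vs 0.658 after round 1).

The same pipeline is scriptable from the shell:

```
evental synth --out corpus --seed 5 --n-documents 60 --n-concepts 5
evental simulate --corpus corpus --strategy informativity --seed 1 --out al.csv
evental rank --corpus corpus          # one-shot ranking under the dev models
evental deficiency --al al.csv --ref rs.csv
```

## Layout

- `src/evental/corpus.py` — data model, standoff I/O, pools, n-grams
- `src/evental/stats.py` — 2×2 tables, chi-square / relative risk / odds ratio, softmax
- `src/evental/informativity.py` — priors, Z scores, posteriors, OOV backoff, combination
- `src/evental/learner.py` — recognizer contract, mock keyword recognizer
- `src/evental/strategies.py` — informativity / committee / entropy / Gibbs / random
- `src/evental/loop.py` — the iterative selection protocol
- `src/evental/evaluation.py` — deficiency, curves, concept-prediction accuracy
- `src/evental/synthetic.py` — seeded corpus and similarity-resource generators
- `docs/methods.md` — modeling choices, parameters and limitations
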