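# Methods

This note records the model, the conventions and the numerical choices the
package implements, and what the synthetic test bed does and does not show.

## Metaphor identification

A token is tested for metaphoricity only if it is a *content word*: coarse
POS in {noun, verb, adjective, adverb}. Auxiliary and copular verbs (be,
have, do, modals) are excluded by the tagger's closed lists: they are
near-ubiquitous and would produce mostly spurious flags. Tokenization,
sentence splitting, tagging and lemmatization are rule-based (regex
tokenizer, terminator-based splitter, function-word lists plus suffix
heuristics, suffix-stripping lemmatizer). This keeps the pipeline
deterministic and dependency-free; it is not a treebank-accuracy tagger,
and no claim is made that its token counts match any particular external
toolchain.

For a detected word *d* in sentence *S*:

1. **Candidate set.** The union, over all ontology senses of *d*'s lemma
   with matching coarse POS, of synonyms and direct hypernyms; plus
   rule-based inflections (plural/3sg, past, gerund, -er/-est, with e-drop,
   consonant doubling and y→i rules) of every member; plus always the
   lemma and surface form of *d* itself. Including *d* makes the literal
   case well defined (best fit = self ⇒ similarity 1). Multiword entries
   are dropped — the algorithm substitutes single tokens. Words absent
   from the ontology degenerate to the self-set and can only be literal.
2. **Best fit.** w\* = argmax over in-vocabulary candidates of the cosine
   between the candidate's *input* vector and the context vector (mean
   input vector of all other in-vocabulary sentence tokens; a symmetric
   window is available, whole-sentence is the default). Ties break to the
   lexicographically smallest word for determinism.
3. **Decision.** The token is metaphorical iff
   cos(output(*d*), output(w\*)) < threshold, strict, threshold 0.5 by
   default. Output vectors, not input vectors, carry the sense-contrast
   comparison; the two matrices are loaded from separate word2vec-text
   files because common training tools export only the input matrix.

Tokens that cannot be scored — detected word out of vocabulary, no
in-vocabulary context, every candidate out of vocabulary — are labeled
`skipped` with a reason, reported separately, and **count as literal** in
document features so that every feature is a total function of the
document. Known failure mode, accepted as designed: fixed collocations
("on my own") can be misflagged because the decision uses only local
embedding context; no collocation filter is applied, though a
stop-collocation list could be layered on by callers.

The union-over-all-senses candidate policy and the inclusion of the word's
own form are implementation decisions where the method description leaves
room; both are fixed here and tested, not asserted as the only reading.

## Sentence sentiment

The scorer is a lexicon scorer with max-magnitude aggregation: positive =
max(1, max positive strength over matched words), negative = min(−1, min
negative strength); overall = positive + negative, 0 = neutral, hence
overall ∈ [−4, 4]. A sentence with no lexicon hits scores (1, −1) →
neutral. Optional negation handling (off by default) flips the
contribution of a strength word preceded within two tokens by a negator.
For fidelity experiments with an external sentence-scoring tool, a second
backend reads precomputed per-sentence scores
(`doc_id,sentence_index,pos,neg`) into the same score type; idiom,
emoticon and repeated-letter heuristics of external tools are out of
scope.

## Features

Fifteen per document, fixed order (`msm.features.FEATURE_ORDER`). Choices
where the definitions were open:

* metaphor sentiment counts are raw counts, not length-normalized
  (a normalized variant sits behind a flag for cross-corpus use);
* each metaphor token inherits its sentence's overall score; neutral
  sentences feed neither the positive nor the negative count;
* the metaphor-sentiment average is per-token (not per sentence containing
  a metaphor) and defaults to 0 — the neutral point — when a document has
  no metaphors;
* fluctuation F is defined as 0 for single-sentence documents (the n−1
  denominator is otherwise undefined);
* the five-dimension lexicon means average over matched tokens only, so
  out-of-lexicon tokens do not dilute toward zero; a document with no
  matches gets 0 on all five dimensions.

Group comparisons use Welch's unequal-variance two-sample t with two-sided
p; positive t means the sick-group mean is larger. The frequent-metaphor
tabulation removes the globally most frequent metaphor lemmas before
ranking each group, so the per-group lists show distinctive rather than
universal vocabulary; ties rank alphabetically.

## SMOTE

Canonical mode interpolates: x_new = x + r·(x_n − x), r ~ U(0,1), x_n one
of the k = 5 nearest minority neighbours by Euclidean distance on the
given (training-fold-standardized) features. Every synthetic point
therefore lies on a segment between two minority points, which the tests
verify by brute force. An `as_printed` mode computes x + r·(x − x_n),
which *extrapolates away* from the neighbour; some write-ups print the
update in that orientation, so it is kept available for comparison, but
interpolation is the default. Oversampling runs inside each training fold
only — applying it before the split would leak interpolants of held-out
points into training.

## Classifier and evaluation

CReLU(x) = concat(max(x,0), max(−x,0)) doubles the width of whatever it is
applied to. The stated layer sizes are the *linear* output dims, with
CReLU applied to the raw input and to each hidden pre-activation:
d → 2d → (100 → 200) → dropout 0.4 → (50 → 100) → 2-way softmax. Training:
Adam (lr 1e-3), batch 16, max 500 epochs, cross-entropy + L2 (λ = 1e-4),
early stopping with patience 20 on a 10 % held-out slice of the training
data, best weights restored. Optimizer, learning rate and epoch budget are
this package's choices; they are exposed as estimator parameters. Features
are z-standardized per training fold (counts and fractions live on very
different scales); the scaler is fit on the training fold only.

Cross-validation is stratified 10-fold (plain k-fold would risk
single-class test folds at study-scale imbalance). Per fold:
standardize → SMOTE the training portion → train → evaluate on the
untouched test fold. Accuracy and F1 (positive class = sick) are averaged
over folds; fold membership is fingerprinted so tests can assert that
resampling never changes test-fold contents. Each of the six conditions is
an independent binary task over the same 15 features.

## Synthetic test bed

`make_embeddings` draws four orthonormal directions (a, b, e, f) from a
seeded QR decomposition (hence dim ≥ 4). Context/topic words and planted
synonyms get input vector a, detected words b, hypernyms −a; output
vectors place metaphorical words at cosine (0.5 − margin)/2 to their
synonym and literal words at (1.5 + margin)/2 — symmetrically outside the
(0.5 − margin, 0.5 + margin) band, re-verified numerically at generation.
Pseudoword suffixes avoid every tagger/lemmatizer suffix rule so all
planted words are tagged noun and survive lemmatization unchanged.

`make_cohort` builds template documents: each sentence fills 5–9 content
slots (a planted metaphorical word with the class's metaphor rate,
otherwise a topic word three times out of four or a planted literal word)
and appends one strength pseudoword that realises the sentence's target
sentiment score exactly; targets are drawn from a discretized normal
around the class mean (sd 1.2), clipped to [−4, 4]. Defaults are
study-scale: 36 sick vs 120 healthy (a prevalence of roughly 36/156,
typical of the per-condition imbalance the method must handle; the
constant `CONDITION_PREVALENCE` records per-condition proportions),
metaphor rates 0.10 vs 0.02, mean sentiment −1 vs +1. The metaphor rate
is defined per content slot: the slot process is exactly Bernoulli, which
is what the generator's binomial self-checks assume; function tokens and
the sentence terminator slightly dilute the per-raw-token rate.

Because topic words dominate sentence contexts, the context vector stays
close to direction a and the identifier recovers planted labels; in dense
sentences where planted (b-direction) words outnumber topic words the
argmax can fall back to the word itself, turning a planted metaphor
literal. This occurs in a small fraction of sentences, attenuates the
realized effect slightly, and is accepted: it perturbs feature values, not
test-fold integrity.

What passing these tests shows: the implementation is internally correct —
the decision rule matches brute-force enumeration exactly, planted
geometry is recovered perfectly, formulas match hand arithmetic, the
resampler and harness have the stated invariants, and the full pipeline
detects planted effects at study-scale sizes while staying at chance on
null data. What it does not show: performance on natural language. The
cohort is a slot grammar over a tiny vocabulary; real corpora have
polysemy, collocations, tagger errors, lexicon gaps and far weaker,
correlated effects, so headline numbers on synthetic cohorts are upper
bounds, not forecasts.

Problem sizes in the test suite and acceptance script (cohorts of ≤ 156
documents, 10–20 seeds, 1000-point resampling checks) are chosen as the
smallest sizes at which the statistical assertions are stable.

## Known limitations

* The ontology backend is the JSON fixture format; hooking a full lexical
  database (e.g. a WordNet reader) means implementing the same
  `Ontology` mapping over it.
* The rule-based tagger/lemmatizer trades accuracy for determinism;
  swapping in a statistical tagger changes token counts and therefore
  feature values.
* The skip-gram trainer is a fixture-scale reference loop (single-threaded
  SGD); corpus-scale embedding training is out of scope.
* The classifier is intentionally small; no attempt is made to tune
  architecture per condition beyond the exposed parameters.
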