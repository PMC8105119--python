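# msm — Metaphor-Sentiment Model

Tools for predicting binary mental-health status (anxiety, depression,
inferiority, sensitivity, social phobia, obsession) from free text, using
two interpretable feature families: **metaphor usage** and **sentence-level
sentiment**. The package is aimed at computational mental-health and
clinical-NLP researchers who want a transparent, feature-based alternative
to end-to-end text classifiers, plus a fully synthetic test bed that
exercises every stage without any external data.

## The method

**Metaphor identification.** Every content word *d* (noun, verb, adjective,
adverb) in a sentence is tested for metaphoricity against a word-embedding
space that provides both *input* and *output* vectors per word (the two
parameter matrices of CBOW / Skip-Gram training). A candidate sense set
*w* is built from *d*'s synonyms and direct hypernyms (plus their
inflections) in a lexical ontology, and the *best-fit* sense is

&nbsp;&nbsp;&nbsp;&nbsp;*w\** = argmax<sub>k ∈ w</sub> cos(v<sub>k</sub>, v<sub>context</sub>),

where v<sub>k</sub> is the candidate's input vector and v<sub>context</sub>
the mean input vector of the other sentence tokens. The token is labeled
**metaphorical** when cos(u<sub>d</sub>, u<sub>w\*</sub>) < 0.5, computed on
output vectors u — i.e. when the word's surface sense differs markedly from
the sense that best fits its context.

**Features (15 per document).** Five metaphor features: the fraction of
metaphor tokens, the probability a sentence contains a metaphor, the counts
of metaphors in positive- and negative-sentiment sentences, and the mean
sentiment score inherited by metaphors. Ten sentiment features: each
sentence gets a strength pair (positive 1..5, negative −5..−1; sum =
overall score, 0 = neutral) from a strength lexicon, yielding the mean
sentence score E = (1/n)ΣS<sub>i</sub>, the fluctuation
F = (1/(n−1))Σ|S<sub>i</sub> − S<sub>i−1</sub>|, the
positive/negative/neutral sentence fractions, and five lexicon means
(pleasantness, attention, sensitivity, aptitude, polarity).

**Classification.** A four-layer fully connected network (hidden output
dims 100 and 50, CReLU activations, dropout 0.4 between hidden layers, L2
penalty, early stopping, 2-way softmax), evaluated by stratified 10-fold
cross-validation with SMOTE minority oversampling applied strictly inside
each training fold. Logistic-regression and RBF-SVM comparators run in the
identical harness.

## Worked example

Generate a synthetic cohort (156 authors, 36 "sick": the sick group writes
with a higher metaphor rate and more negative sentiment), extract features
and cross-validate:

```bash
msm synth --preset cohort --seed 3 --out data
msm features --input data/docs \
    --embeddings-in data/embeddings_input.txt \
    --embeddings-out data/embeddings_output.txt \
    --ontology data/ontology.json \
    --strength data/strength_lexicon.csv \
    --sentic data/sentic_lexicon.csv \
    --out features.csv
msm train --features features.csv --labels data/labels.csv \
    --condition depression --sets all --seed 0 --out results.json
```

prints

```
wrote 156x15 feature table to features.csv
depression [all]: accuracy=0.994 f1=0.989
```

meaning the 10-fold cross-validated classifier recovers the planted
sick/healthy contrast almost perfectly from the 15 features. The
metaphor identifier itself can be checked against planted ground truth:

```bash
msm synth --preset planted-metaphor --seed 3 --out pm
msm identify --input pm/docs \
    --embeddings-in pm/embeddings_input.txt \
    --embeddings-out pm/embeddings_output.txt \
    --ontology pm/ontology.json --gold pm/gold.csv --report report.csv
# precision=1.000 recall=1.000 f1=1.000
```

Every token decision is written to `report.csv`, e.g.
`planted,0,4,metbb,synmetbb,0.1000,metaphorical`: the detected word's
output-vector similarity to its best-fit sense (0.10) falls below the 0.5
threshold, so it is flagged.

The same pipeline is available as a library: see
`msm.MetaphorAnnotator`, `msm.MetaphorSentimentFeaturizer`, `msm.SMOTE`
and `msm.MSMClassifier`, which follow scikit-learn estimator conventions.

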