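"""Document feature sets: 5 metaphor features and 10 sentiment features.

Metaphor features (per document):

* ``pct_metaphor_tokens`` — metaphor-labeled tokens / total tokens;
* ``prob_sentence_with_metaphor`` — sentences containing at least one
  metaphor / number of sentences;
* ``n_pos_metaphor`` / ``n_neg_metaphor`` — counts of metaphor tokens whose
  sentence has positive / negative overall sentiment (each metaphor inherits
  the overall score of its sentence; neutral sentences feed neither count);
* ``avg_metaphor_sentiment`` — mean inherited score over metaphor tokens
  (0 when the document has none).

Sentiment features:

* five sentic-dimension means (pleasantness, attention, sensitivity,
  aptitude, polarity) over lexicon-matched tokens;
* fractions of positive / negative / neutral sentences (they sum to 1);
* ``avg_sentence_sentiment`` E — the mean of the per-sentence overall
  scores, E = (1/n) * sum_i S_i;
* ``fluctuation`` F — the mean absolute difference of consecutive sentence
  scores, F = (1/(n-1)) * sum_{i=2..n} |S_i - S_{i-1}|, defined as 0 for
  single-sentence documents.

The fixed 15-column order is :data:`FEATURE_ORDER`; subsets "meta" and
"sent" select the first five and last ten columns respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Document, LabelTable
from .lexicons import SENTIC_DIMS, SenticLexicon

__all__ = [
    "METAPHOR_FEATURES",
    "SENTIMENT_FEATURES",
    "FEATURE_ORDER",
    "MetaphorFeatures",
    "SentimentFeatures",
    "MetaphorSentimentFeaturizer",
    "metaphor_features",
    "sentiment_features",
    "feature_vector",
    "build_matrix",
    "subset_columns",
    "group_compare",
    "frequent_metaphors",
]

METAPHOR_FEATURES = (
    "pct_metaphor_tokens",
    "prob_sentence_with_metaphor",
    "n_pos_metaphor",
    "n_neg_metaphor",
    "avg_metaphor_sentiment",
)
SENTIMENT_FEATURES = (
    "mean_pleasantness",
    "mean_attention",
    "mean_sensitivity",
    "mean_aptitude",
    "mean_polarity",
    "frac_pos_sentences",
    "frac_neg_sentences",
    "frac_neutral_sentences",
    "avg_sentence_sentiment",
    "fluctuation",
)
FEATURE_ORDER = METAPHOR_FEATURES + SENTIMENT_FEATURES

FEATURE_SETS = {
    "meta": METAPHOR_FEATURES,
    "sent": SENTIMENT_FEATURES,
    "all": FEATURE_ORDER,
}


@dataclass
class MetaphorFeatures:
    pct_metaphor_tokens: float
    prob_sentence_with_metaphor: float
    n_pos_metaphor: int
    n_neg_metaphor: int
    avg_metaphor_sentiment: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in METAPHOR_FEATURES)


@dataclass
class SentimentFeatures:
    mean_pleasantness: float
    mean_attention: float
    mean_sensitivity: float
    mean_aptitude: float
    mean_polarity: float
    frac_pos_sentences: float
    frac_neg_sentences: float
    frac_neutral_sentences: float
    avg_sentence_sentiment: float
    fluctuation: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in SENTIMENT_FEATURES)


def _require_scored(doc: Document) -> None:
    for sent in doc.sentences:
        if sent.sentiment is None:
            raise ValueError(f"document {doc.doc_id!r} has unscored sentences")


def metaphor_features(
    doc: Document, *, normalize_counts: bool = False
) -> MetaphorFeatures:
    """Compute the 5 metaphor features of an annotated, scored document.

    With ``normalize_counts`` the positive/negative metaphor counts are
    divided by the total token count (off by default; the canonical
    features are raw counts).
    """
    _require_scored(doc)
    n_tokens = doc.n_tokens
    n_metaphor = 0
    sentences_with = 0
    inherited: list[int] = []
    n_pos = n_neg = 0
    for sent in doc.sentences:
        decisions = sent.metaphor
        if decisions is None:
            raise ValueError(f"document {doc.doc_id!r} is not metaphor-annotated")
        n_here = sum(1 for d in decisions.values() if d.is_metaphorical)
        if n_here:
            sentences_with += 1
        overall = sent.sentiment.overall
        n_metaphor += n_here
        inherited.extend([overall] * n_here)
        if overall > 0:
            n_pos += n_here
        elif overall < 0:
            n_neg += n_here
    scale = 1.0 / n_tokens if normalize_counts else 1.0
    return MetaphorFeatures(
        pct_metaphor_tokens=n_metaphor / n_tokens,
        prob_sentence_with_metaphor=sentences_with / doc.n_sentences,
        n_pos_metaphor=n_pos * scale if normalize_counts else n_pos,
        n_neg_metaphor=n_neg * scale if normalize_counts else n_neg,
        avg_metaphor_sentiment=float(np.mean(inherited)) if inherited else 0.0,
    )


def sentiment_features(doc: Document, sentic: SenticLexicon) -> SentimentFeatures:
    """Compute the 10 sentiment features of a scored document.

    The five sentic means average over lexicon-matched tokens only;
    documents with no matches get 0 on all five dimensions.
    """
    _require_scored(doc)
    scores = [s.sentiment.overall for s in doc.sentences]
    n = len(scores)
    e_value = float(np.mean(scores))
    if n > 1:
        fluct = float(np.mean(np.abs(np.diff(scores))))
    else:
        fluct = 0.0
    n_pos = sum(1 for s in scores if s > 0)
    n_neg = sum(1 for s in scores if s < 0)
    n_neu = n - n_pos - n_neg

    matched: list[tuple[float, ...]] = []
    for sent in doc.sentences:
        for tok in sent.tokens:
            entry = sentic.lookup(tok)
            if entry is not None:
                matched.append(entry.values())
    if matched:
        means = np.mean(np.asarray(matched), axis=0)
    else:
        means = np.zeros(len(SENTIC_DIMS))

    return SentimentFeatures(
        mean_pleasantness=float(means[0]),
        mean_attention=float(means[1]),
        mean_sensitivity=float(means[2]),
        mean_aptitude=float(means[3]),
        mean_polarity=float(means[4]),
        frac_pos_sentences=n_pos / n,
        frac_neg_sentences=n_neg / n,
        frac_neutral_sentences=n_neu / n,
        avg_sentence_sentiment=e_value,
        fluctuation=fluct,
    )


def feature_vector(doc: Document, sentic: SenticLexicon) -> dict[str, float]:
    """The full named 15-feature vector of one document (fixed order)."""
    meta = metaphor_features(doc)
    sent = sentiment_features(doc, sentic)
    values = meta.as_tuple() + sent.as_tuple()
    return dict(zip(FEATURE_ORDER, (float(v) for v in values)))


class MetaphorSentimentFeaturizer:
    """Transformer mapping annotated, scored documents to the 15-feature matrix.

    ``transform`` returns a :class:`pandas.DataFrame` indexed by ``doc_id``
    with columns in :data:`FEATURE_ORDER` (optionally restricted to the
    "meta" or "sent" subset). Stateless; ``fit`` returns self.
    """

    def __init__(self, sentic: SenticLexicon, feature_set: str = "all"):
        self.sentic = sentic
        self.feature_set = feature_set

    def get_params(self, deep: bool = True) -> dict:
        return {"sentic": self.sentic, "feature_set": self.feature_set}

    def set_params(self, **params) -> "MetaphorSentimentFeaturizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "MetaphorSentimentFeaturizer":
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {sorted(FEATURE_SETS)}")
        return self

    def transform(self, documents: list[Document]) -> pd.DataFrame:
        self.fit()
        rows = {d.doc_id: feature_vector(d, self.sentic) for d in documents}
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame = frame[list(FEATURE_ORDER)]
        frame.index.name = "doc_id"
        return frame[list(FEATURE_SETS[self.feature_set])]


def subset_columns(frame: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    """Restrict a full feature frame to the meta / sent / all columns."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {sorted(FEATURE_SETS)}")
    return frame[list(FEATURE_SETS[feature_set])]


def build_matrix(
    docs: list[Document],
    labels: LabelTable,
    condition: str,
    sentic: SenticLexicon,
    feature_set: str = "all",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Row-aligned feature matrix and boolean sick/not-sick label vector."""
    frame = MetaphorSentimentFeaturizer(sentic, feature_set).transform(docs)
    label_map = labels.labels_for(condition)
    missing = [d for d in frame.index if d not in label_map]
    if missing:
        raise ValueError(
            f"no {condition} label for documents: {missing[:10]}"
        )
    y = np.array([label_map[d] for d in frame.index], dtype=bool)
    return frame, y


def group_compare(X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    """Per-feature two-sample comparison between sick and not-sick groups.

    Uses the unequal-variance (Welch) two-sample t statistic with a
    two-sided p value; positive t means the sick group mean is larger.
    Features that are degenerate in either group (zero variance in both, or
    a group smaller than 2) are flagged with NaN statistics.
    """
    y = np.asarray(y, dtype=bool)
    sick, healthy = X[y], X[~y]
    if len(sick) < 2 or len(healthy) < 2:
        raise ValueError("both groups need at least 2 members")
    records = []
    for col in X.columns:
        a = sick[col].to_numpy(dtype=float)
        b = healthy[col].to_numpy(dtype=float)
        if a.std() == 0 and b.std() == 0:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        records.append(
            {
                "feature": col,
                "mean_sick": a.mean(),
                "mean_not_sick": b.mean(),
                "t": float(t) if np.isfinite(t) else t,
                "p": float(p) if np.isfinite(p) else p,
            }
        )
    return pd.DataFrame.from_records(records).set_index("feature")


def frequent_metaphors(
    groups: dict[str, list[Document]],
    top_k: int = 10,
    global_exclude_k: int = 0,
) -> dict[str, list[tuple[str, int]]]:
    """Rank metaphor-labeled lemmas per group, excluding corpus-wide staples.

    The ``global_exclude_k`` most frequent metaphor lemmas over *all* groups
    combined are removed before the per-group ranking, so each group's list
    shows what is distinctive rather than what everyone writes. Ties rank
    alphabetically.
    """
    per_group: dict[str, dict[str, int]] = {}
    total: dict[str, int] = {}
    for name, docs in groups.items():
        counts: dict[str, int] = {}
        for doc in docs:
            for sent in doc.sentences:
                if sent.metaphor is None:
                    raise ValueError(f"document {doc.doc_id!r} is not annotated")
                for dec in sent.metaphor.values():
                    if dec.is_metaphorical:
                        counts[dec.detected] = counts.get(dec.detected, 0) + 1
                        total[dec.detected] = total.get(dec.detected, 0) + 1
        per_group[name] = counts

    ranked_total = sorted(total.items(), key=lambda kv: (-kv[1], kv[0]))
    excluded = {w for w, _ in ranked_total[:global_exclude_k]}

    out: dict[str, list[tuple[str, int]]] = {}
    for name, counts in per_group.items():
        kept = [(w, c) for w, c in counts.items() if w not in excluded]
        kept.sort(key=lambda kv: (-kv[1], kv[0]))
        out[name] = kept[:top_k]
    return out
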