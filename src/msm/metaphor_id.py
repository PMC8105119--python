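"""Token-level metaphor identification by best-fit-sense comparison.

For every content word (the *detected* word) in a sentence the identifier:

1. builds the candidate sense set — the word itself plus synonyms, direct
   hypernyms and their inflections from the ontology;
2. selects the *best fit* word ``w* = argmax_k cos(v_k, v_context)`` over
   in-vocabulary candidates ``k``, where ``v_k`` is the candidate's input
   vector and ``v_context`` the mean input vector of the other sentence
   tokens — the candidate whose sense best matches the context;
3. compares the *output* vectors of the detected word and the best fit:
   when their cosine similarity falls below the threshold (default 0.5,
   strict ``<``) the surface sense differs enough from the contextual sense
   that the token is labeled metaphorical.

Words that cannot be scored (detected word out of vocabulary, no
in-vocabulary context, all candidates out of vocabulary) are labeled
``skipped`` with a reason and count as literal downstream, so document
features remain total.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import Document, Sentence, Token
from .embeddings import EmbeddingStore, NoContextError, context_vector, cosine
from .lexicons import CandidateSet, Ontology, candidate_set

logger = logging.getLogger(__name__)

__all__ = [
    "MetaphorDecision",
    "EvalReport",
    "MetaphorAnnotator",
    "best_fit",
    "decide",
    "annotate_document",
    "evaluate",
    "read_gold_annotations",
]

DEFAULT_THRESHOLD = 0.5


@dataclass
class MetaphorDecision:
    detected: str
    best_fit: str | None
    sim_best_fit_context: float | None
    sim_detected_bestfit: float | None
    threshold: float
    label: str  # metaphorical | literal | skipped
    skip_reason: str | None = None

    @property
    def is_metaphorical(self) -> bool:
        return self.label == "metaphorical"


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


def best_fit(
    detected: Token,
    sentence: Sentence,
    store: EmbeddingStore,
    candidates: CandidateSet,
    *,
    window: int = 0,
) -> tuple[str, float]:
    """Select the candidate with maximal input-vector cosine to the context.

    Ties are broken toward the lexicographically smallest word so the
    selection is deterministic. Raises ``LookupError`` when every candidate
    is out of vocabulary and ``NoContextError`` when the context is.
    """
    ctx = context_vector(sentence, detected.index, store, window=window)
    best_word: str | None = None
    best_sim = -2.0
    for word in sorted(candidates.candidates):
        if word not in store:
            continue
        sim = cosine(store.input_vector(word), ctx)
        if sim > best_sim:
            best_word, best_sim = word, sim
    if best_word is None:
        raise LookupError(
            f"no candidate of {candidates.detected!r} is in the embedding vocabulary"
        )
    return best_word, best_sim


def decide(
    detected: Token,
    sentence: Sentence,
    store: EmbeddingStore,
    ontology: Ontology,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    window: int = 0,
) -> MetaphorDecision:
    """Full metaphor decision for one content token.

    The label is ``metaphorical`` iff the output-vector cosine between the
    detected word and its best fit is strictly below the threshold.
    """
    if not detected.is_content:
        raise ValueError(f"{detected.surface!r} is not a content word")
    key = store.resolve(detected)
    if key is None:
        return _skipped(detected, threshold, "detected word out of vocabulary")
    candidates = candidate_set(detected, ontology)
    try:
        w_star, sim_ctx = best_fit(
            detected, sentence, store, candidates, window=window
        )
    except NoContextError:
        return _skipped(detected, threshold, "no in-vocabulary context")
    except LookupError:
        return _skipped(detected, threshold, "all candidates out of vocabulary")
    sim_out = cosine(store.output_vector(key), store.output_vector(w_star))
    label = "metaphorical" if sim_out < threshold else "literal"
    return MetaphorDecision(
        detected=detected.lemma,
        best_fit=w_star,
        sim_best_fit_context=sim_ctx,
        sim_detected_bestfit=sim_out,
        threshold=threshold,
        label=label,
    )


def _skipped(detected: Token, threshold: float, reason: str) -> MetaphorDecision:
    logger.debug("skipping %r: %s", detected.surface, reason)
    return MetaphorDecision(
        detected=detected.lemma,
        best_fit=None,
        sim_best_fit_context=None,
        sim_detected_bestfit=None,
        threshold=threshold,
        label="skipped",
        skip_reason=reason,
    )


class MetaphorAnnotator:
    """Transformer that labels every content token of documents.

    scikit-learn style: stateless ``fit`` (the resources are constructor
    parameters), ``transform`` maps documents to annotated documents whose
    sentences carry a parallel ``metaphor`` decision list.

    Parameters
    ----------
    store : EmbeddingStore
        Paired input/output vectors.
    ontology : Ontology
        Synonym/hypernym source for candidate sets.
    threshold : float, default 0.5
        Output-vector cosine below which a token is metaphorical.
    window : int, default 0
        Context window; 0 means the whole sentence.
    """

    def __init__(
        self,
        store: EmbeddingStore,
        ontology: Ontology,
        threshold: float = DEFAULT_THRESHOLD,
        window: int = 0,
    ):
        self.store = store
        self.ontology = ontology
        self.threshold = threshold
        self.window = window

    def get_params(self, deep: bool = True) -> dict:
        return {
            "store": self.store,
            "ontology": self.ontology,
            "threshold": self.threshold,
            "window": self.window,
        }

    def set_params(self, **params) -> "MetaphorAnnotator":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "MetaphorAnnotator":
        return self

    def transform(self, documents: list[Document]) -> list[Document]:
        for doc in documents:
            self.annotate(doc)
        return documents

    def annotate(self, doc: Document) -> Document:
        """Attach per-sentence decision lists in place; idempotent."""
        for sent in doc.sentences:
            decisions: dict[int, MetaphorDecision] = {}
            for tok in sent.content_tokens():
                decisions[tok.index] = decide(
                    tok,
                    sent,
                    self.store,
                    self.ontology,
                    self.threshold,
                    window=self.window,
                )
            sent.metaphor = decisions
        return doc


def annotate_document(
    doc: Document,
    store: EmbeddingStore,
    ontology: Ontology,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    window: int = 0,
) -> Document:
    """Function-style wrapper over :class:`MetaphorAnnotator`."""
    return MetaphorAnnotator(store, ontology, threshold, window).annotate(doc)


# --------------------------------------------------------------------------
# Evaluation against gold token annotations
# --------------------------------------------------------------------------

def read_gold_annotations(path: str | Path) -> dict[tuple[str, int, int], str]:
    """Read gold CSV ``doc_id,sentence_index,token_index,label``."""
    gold: dict[tuple[str, int, int], str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"doc_id", "sentence_index", "token_index", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"gold file must have columns {sorted(required)}")
        for row in reader:
            label = row["label"].strip()
            if label not in ("metaphorical", "literal"):
                raise ValueError(f"unknown gold label {label!r}")
            gold[(row["doc_id"], int(row["sentence_index"]),
                  int(row["token_index"]))] = label
    return gold


def evaluate(
    gold: dict[tuple[str, int, int], str],
    documents: list[Document],
) -> EvalReport:
    """Token-level precision/recall/F1 with *metaphorical* as positive class.

    Skipped tokens count as literal predictions. Gold keys that match no
    annotated token are an error listing the offenders.
    """
    predicted: dict[tuple[str, int, int], str] = {}
    for doc in documents:
        for si, sent in enumerate(doc.sentences):
            decisions = getattr(sent, "metaphor", None)
            if decisions is None:
                raise ValueError(f"document {doc.doc_id!r} is not annotated")
            for ti, dec in decisions.items():
                predicted[(doc.doc_id, si, ti)] = (
                    "metaphorical" if dec.is_metaphorical else "literal"
                )
    missing = sorted(k for k in gold if k not in predicted)
    if missing:
        raise ValueError(f"gold ids with no prediction: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    tp = fp = tn = fn = 0
    for key, g in gold.items():
        p = predicted[key]
        if g == "metaphorical" and p == "metaphorical":
            tp += 1
        elif g == "metaphorical":
            fn += 1
        elif p == "metaphorical":
            fp += 1
        else:
            tn += 1
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn)
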