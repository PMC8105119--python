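"""Lexical resources: sentiment strength, sentic dimensions, and the ontology.

Three resources feed the pipeline:

* a **strength lexicon** mapping words to a positive strength in 1..5 and a
  negative strength in -5..-1 (the per-sentence scoring convention: the
  sentence's positive score is the max positive strength over matched words,
  floored at 1; the negative score is the min negative strength, capped at
  -1; their sum is the overall score and 0 means neutral);
* a **sentic lexicon** mapping words to five affective dimensions
  (pleasantness, attention, sensitivity, aptitude, polarity), each in [-1, 1];
* a **lexical ontology** providing, per word and coarse POS, synonyms and
  direct hypernyms, from which candidate sense sets are built.

The ontology backend is a JSON fixture of the form
``{word: {pos: {"synonyms": [...], "hypernyms": [...]}}}``; candidate sets
take the union over all senses (all listed synonyms/hypernyms for the
matching POS), add rule-based inflections, drop multiword entries, and
always contain the detected word itself.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .corpus_io import Sentence, SentimentScore, Token

logger = logging.getLogger(__name__)

__all__ = [
    "StrengthLexicon",
    "SenticEntry",
    "SenticLexicon",
    "Ontology",
    "CandidateSet",
    "sentence_sentiment",
    "candidate_set",
    "inflections",
    "load_strength_lexicon",
    "load_sentic_lexicon",
    "load_ontology",
]

_NEGATORS = frozenset({"not", "no", "never", "n't", "cannot", "nothing"})


# --------------------------------------------------------------------------
# Strength lexicon
# --------------------------------------------------------------------------

@dataclass
class StrengthLexicon:
    """word -> (pos_strength in 1..5, neg_strength in -5..-1)."""

    entries: dict[str, tuple[int, int]] = field(default_factory=dict)

    def add(self, word: str, pos_strength: int, neg_strength: int) -> None:
        if not 1 <= pos_strength <= 5:
            raise ValueError(
                f"{word!r}: pos_strength {pos_strength} outside [1, 5]"
            )
        if not -5 <= neg_strength <= -1:
            raise ValueError(
                f"{word!r}: neg_strength {neg_strength} outside [-5, -1]"
            )
        key = word.lower()
        if key in self.entries:
            logger.warning("duplicate strength entry for %r: last wins", word)
        self.entries[key] = (pos_strength, neg_strength)

    def lookup(self, token: Token) -> tuple[int, int] | None:
        hit = self.entries.get(token.surface.lower())
        if hit is None:
            hit = self.entries.get(token.lemma)
        return hit

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def sentence_sentiment(
    sentence: Sentence,
    lex: StrengthLexicon,
    *,
    handle_negation: bool = False,
) -> SentimentScore:
    """Score one sentence with the strength lexicon.

    positive = max(1, max matched pos_strength); negative = min(-1, min
    matched neg_strength); with no matches the floor pair (1, -1) gives an
    overall of 0, i.e. neutral. With ``handle_negation`` a strength word
    preceded within two tokens by a negator contributes with flipped sign
    (its positive strength feeds the negative side and vice versa).
    """
    pos, neg = 1, -1
    toks = sentence.tokens
    for i, tok in enumerate(toks):
        hit = lex.lookup(tok)
        if hit is None:
            continue
        p, n = hit
        negated = handle_negation and any(
            toks[j].surface.lower() in _NEGATORS
            for j in range(max(0, i - 2), i)
        )
        if negated:
            p, n = -n, -p
        pos = max(pos, p)
        neg = min(neg, n)
    return SentimentScore(positive=pos, negative=neg)


def score_document(
    doc,
    lex: StrengthLexicon,
    *,
    handle_negation: bool = False,
) -> None:
    """Attach a SentimentScore to every sentence of *doc* in place."""
    for sent in doc.sentences:
        sent.sentiment = sentence_sentiment(
            sent, lex, handle_negation=handle_negation
        )


def load_strength_lexicon(path: str | Path) -> StrengthLexicon:
    """Load CSV/TSV ``word,pos_strength,neg_strength`` with a header row."""
    lex = StrengthLexicon()
    for lineno, row in _read_delimited(path, ("word", "pos_strength", "neg_strength")):
        try:
            lex.add(row["word"], int(row["pos_strength"]), int(row["neg_strength"]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return lex


# --------------------------------------------------------------------------
# Sentic lexicon
# --------------------------------------------------------------------------

SENTIC_DIMS = ("pleasantness", "attention", "sensitivity", "aptitude", "polarity")


@dataclass
class SenticEntry:
    word: str
    pleasantness: float
    attention: float
    sensitivity: float
    aptitude: float
    polarity: float

    def __post_init__(self) -> None:
        for dim in SENTIC_DIMS:
            v = getattr(self, dim)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{self.word!r}: {dim} {v} outside [-1, 1]")

    def values(self) -> tuple[float, ...]:
        return tuple(getattr(self, d) for d in SENTIC_DIMS)


@dataclass
class SenticLexicon:
    entries: dict[str, SenticEntry] = field(default_factory=dict)

    def add(self, entry: SenticEntry) -> None:
        key = entry.word.lower()
        if key in self.entries:
            logger.warning("duplicate sentic entry for %r: last wins", entry.word)
        self.entries[key] = entry

    def lookup(self, token: Token) -> SenticEntry | None:
        hit = self.entries.get(token.surface.lower())
        if hit is None:
            hit = self.entries.get(token.lemma)
        return hit

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_sentic_lexicon(path: str | Path) -> SenticLexicon:
    """Load CSV ``word,pleasantness,attention,sensitivity,aptitude,polarity``."""
    lex = SenticLexicon()
    cols = ("word",) + SENTIC_DIMS
    for lineno, row in _read_delimited(path, cols):
        try:
            lex.add(
                SenticEntry(
                    word=row["word"].lower(),
                    **{d: float(row[d]) for d in SENTIC_DIMS},
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return lex


def _read_delimited(path: str | Path, required: tuple[str, ...]):
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.readline()
        delim = "\t" if "\t" in sample else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not set(required) <= set(reader.fieldnames):
            raise ValueError(f"{path}: header must name columns {list(required)}")
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) in (None, "") for c in required):
                raise ValueError(f"{path}:{lineno}: malformed row {row}")
            yield lineno, row


# --------------------------------------------------------------------------
# Ontology and candidate sets
# --------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """All candidate senses for a detected word, with provenance."""

    detected: str
    candidates: set[str]
    provenance: dict[str, str]
    degenerate: bool = False  # True when the ontology had no entry

    def __post_init__(self) -> None:
        if self.detected not in self.candidates:
            raise ValueError("candidate set must contain the detected word")


@dataclass
class Ontology:
    """word -> pos -> {"synonyms": [...], "hypernyms": [...]}."""

    entries: dict[str, dict[str, dict[str, list[str]]]] = field(default_factory=dict)

    def senses(self, lemma: str, pos: str) -> dict[str, list[str]] | None:
        by_pos = self.entries.get(lemma.lower())
        if by_pos is None:
            return None
        return by_pos.get(pos)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries


def load_ontology(path: str | Path) -> Ontology:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    entries: dict[str, dict[str, dict[str, list[str]]]] = {}
    for word, by_pos in raw.items():
        entries[word.lower()] = {
            pos: {
                "synonyms": [w.lower() for w in rel.get("synonyms", [])],
                "hypernyms": [w.lower() for w in rel.get("hypernyms", [])],
            }
            for pos, rel in by_pos.items()
        }
    return Ontology(entries=entries)


def inflections(word: str) -> set[str]:
    """Rule-based inflected forms: plural/3sg, past, gerund, -er/-est.

    Applies e-drop, consonant doubling and y->i rules; no morphology
    database is consulted.
    """
    out: set[str] = set()
    w = word.lower()
    if not w.isalpha() or len(w) < 2:
        return out
    last, penult = w[-1], w[-2] if len(w) >= 2 else ""

    # plural / third person singular
    if last in "sxz" or w.endswith(("ch", "sh")):
        out.add(w + "es")
    elif last == "y" and penult not in _V:
        out.add(w[:-1] + "ies")
    else:
        out.add(w + "s")

    doubled = (
        len(w) >= 3
        and last not in _V + "wxy"
        and penult in _V
        and w[-3] not in _V
    )

    # past tense
    if last == "e":
        out.add(w + "d")
    elif last == "y" and penult not in _V:
        out.add(w[:-1] + "ied")
    else:
        if doubled:
            out.add(w + last + "ed")
        out.add(w + "ed")

    # gerund
    if last == "e" and not w.endswith(("ee", "oe", "ye")):
        out.add(w[:-1] + "ing")
    else:
        if doubled:
            out.add(w + last + "ing")
        out.add(w + "ing")

    # comparative / superlative
    if last == "e":
        out.add(w + "r")
        out.add(w + "st")
    elif last == "y" and penult not in _V:
        out.add(w[:-1] + "ier")
        out.add(w[:-1] + "iest")
    else:
        if doubled:
            out.add(w + last + "er")
            out.add(w + last + "est")
        out.add(w + "er")
        out.add(w + "est")
    return out


_V = "aeiou"


def candidate_set(detected: Token, ontology: Ontology) -> CandidateSet:
    """Build the candidate sense set for a detected content word.

    Union over all senses of the detected word's lemma with matching coarse
    POS: synonyms, direct hypernyms, and rule-based inflections of all of
    them (and of the lemma itself). Multiword entries are dropped. The set
    always contains the detected lemma (and surface form), so downstream
    best-fit search never ranges over an empty set; a word absent from the
    ontology yields the degenerate singleton-style set.
    """
    if not detected.is_content:
        raise ValueError(f"{detected.surface!r} is not a content word")
    lemma = detected.lemma.lower()
    surface = detected.surface.lower()
    provenance: dict[str, str] = {lemma: "self"}
    candidates: set[str] = {lemma}
    if surface != lemma and " " not in surface:
        candidates.add(surface)
        provenance[surface] = "self"

    senses = ontology.senses(lemma, detected.pos)
    degenerate = senses is None
    synonyms = [] if senses is None else senses.get("synonyms", [])
    hypernyms = [] if senses is None else senses.get("hypernyms", [])

    def _add(words: Iterable[str], kind: str) -> None:
        for w in words:
            w = w.lower()
            if " " in w or "_" in w:  # multiword senses are out of scope
                continue
            if w not in candidates:
                candidates.add(w)
                provenance[w] = kind
            for inf in inflections(w):
                if inf not in candidates:
                    candidates.add(inf)
                    provenance[inf] = f"inflection-of-{kind}"

    # inflections of the detected lemma itself
    for inf in inflections(lemma):
        if inf not in candidates:
            candidates.add(inf)
            provenance[inf] = "self"
    _add(synonyms, "synonym")
    _add(hypernyms, "hypernym")

    return CandidateSet(
        detected=lemma,
        candidates=candidates,
        provenance=provenance,
        degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# Precomputed per-sentence scores (external-tool fidelity backend)
# --------------------------------------------------------------------------

def load_precomputed_scores(path: str | Path) -> dict[tuple[str, int], SentimentScore]:
    """Read CSV ``doc_id,sentence_index,pos,neg`` of externally computed scores."""
    scores: dict[tuple[str, int], SentimentScore] = {}
    for lineno, row in _read_delimited(path, ("doc_id", "sentence_index", "pos", "neg")):
        pos, neg = int(row["pos"]), int(row["neg"])
        if not 1 <= pos <= 5 or not -5 <= neg <= -1:
            raise ValueError(f"{path}:{lineno}: scores out of range ({pos}, {neg})")
        scores[(row["doc_id"], int(row["sentence_index"]))] = SentimentScore(
            positive=pos, negative=neg
        )
    return scores


def apply_precomputed_scores(doc, scores: Mapping[tuple[str, int], SentimentScore]) -> None:
    """Attach precomputed scores to *doc*; missing sentences raise KeyError."""
    for i, sent in enumerate(doc.sentences):
        key = (doc.doc_id, i)
        if key not in scores:
            raise KeyError(f"no precomputed score for {key}")
        sent.sentiment = scores[key]
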