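"""Document model and plain-text ingestion.

Turns raw UTF-8 text into the internal document representation used by the
rest of the pipeline: sentences of tokens, each token carrying a coarse
part-of-speech tag, a lemma, and a content-word flag. Content words (nouns,
verbs, adjectives, adverbs) are the candidates for metaphor detection.

Tokenization, sentence splitting, tagging and lemmatization are rule-based
and fully deterministic: byte-identical input yields an identical token
stream. The tagger is intentionally lightweight — closed-class function-word
lists plus suffix heuristics — which is sufficient for the content/function
distinction the pipeline needs; it is not a treebank-accuracy tagger.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Token",
    "SentimentScore",
    "Sentence",
    "Document",
    "WritingRecord",
    "LabelTable",
    "CONDITIONS",
    "EmptyDocumentError",
    "parse_document",
    "merge_user_records",
    "read_labels",
    "document_to_json",
    "document_from_json",
]

CONDITIONS = (
    "anxiety",
    "depression",
    "inferiority",
    "sensitivity",
    "social_phobia",
    "obsession",
)

CONTENT_POS = frozenset({"noun", "verb", "adjective", "adverb"})


class EmptyDocumentError(ValueError):
    """Raised when a document is empty after whitespace stripping."""


@dataclass
class Token:
    surface: str
    lemma: str
    pos: str  # noun | verb | adjective | adverb | other
    is_content: bool
    index: int

    def __post_init__(self) -> None:
        if self.is_content != (self.pos in CONTENT_POS):
            raise ValueError(
                f"is_content must mirror pos for {self.surface!r} ({self.pos})"
            )


@dataclass
class SentimentScore:
    """Sentence-level strength pair: positive in 1..5, negative in -5..-1.

    ``overall`` is their sum; 0 is neutral.
    """

    positive: int
    negative: int

    @property
    def overall(self) -> int:
        return self.positive + self.negative

    @property
    def is_neutral(self) -> bool:
        return self.overall == 0


@dataclass
class Sentence:
    tokens: list[Token]
    sentiment: SentimentScore | None = None
    # token index -> metaphor decision, filled by the annotator
    metaphor: dict | None = None

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("a sentence must contain at least one token")

    def content_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.is_content]


@dataclass
class Document:
    doc_id: str
    sentences: list[Sentence]

    def __post_init__(self) -> None:
        if not self.sentences:
            raise EmptyDocumentError(f"document {self.doc_id!r} has no sentences")

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s.tokens) for s in self.sentences)


@dataclass
class WritingRecord:
    """One dated posting by a user (eRisk-style writing history entry)."""

    user_id: str
    timestamp: datetime | str
    title: str
    body: str

    def parsed_timestamp(self) -> datetime:
        if isinstance(self.timestamp, datetime):
            return self.timestamp
        try:
            return datetime.fromisoformat(self.timestamp)
        except ValueError as exc:
            raise ValueError(
                f"record for user {self.user_id!r} has unparseable "
                f"timestamp {self.timestamp!r}"
            ) from exc


@dataclass
class LabelTable:
    """Binary sick/not-sick labels per (document, condition) pair."""

    rows: list[tuple[str, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for doc_id, condition, _sick in self.rows:
            if condition not in CONDITIONS:
                raise ValueError(
                    f"unknown condition {condition!r}; valid conditions are "
                    + ", ".join(CONDITIONS)
                )
            key = (doc_id, condition)
            if key in seen:
                raise ValueError(f"duplicate label for {key}")
            seen.add(key)

    def labels_for(self, condition: str) -> dict[str, bool]:
        if condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {condition!r}; valid conditions are "
                + ", ".join(CONDITIONS)
            )
        return {d: s for d, c, s in self.rows if c == condition}


# --------------------------------------------------------------------------
# Tokenization / tagging
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?|\d+(?:\.\d+)?|[^\w\s]")

# Sentence boundary: terminator(s) followed by whitespace, or end of text.
_SENT_RE = re.compile(r"[^.!?]*[.!?]+(?:\s+|$)|[^.!?]+$")

_DETERMINERS = {"a", "an", "the", "this", "that", "these", "those"}
_PRONOUNS = {
    "i", "you", "he", "she", "it", "we", "they", "me", "him", "her", "us",
    "them", "my", "your", "his", "its", "our", "their", "mine", "yours",
    "hers", "ours", "theirs", "myself", "yourself", "himself", "herself",
    "itself", "ourselves", "themselves", "who", "whom", "whose", "which",
    "what", "someone", "anyone", "everyone", "nothing", "something",
    "anything", "everything",
}
_PREPOSITIONS = {
    "in", "on", "at", "by", "for", "with", "about", "against", "between",
    "into", "through", "during", "before", "after", "above", "below", "to",
    "from", "up", "down", "of", "off", "over", "under", "near", "without",
    "within", "among", "toward", "towards", "upon", "onto",
}
_CONJUNCTIONS = {
    "and", "or", "but", "nor", "so", "yet", "if", "because", "although",
    "while", "when", "where", "since", "unless", "until", "whether", "as",
    "than", "though",
}
_AUXILIARIES = {
    "be", "am", "is", "are", "was", "were", "been", "being",
    "have", "has", "had", "having", "do", "does", "did", "doing",
    "will", "would", "shall", "should", "can", "could", "may", "might",
    "must", "ought",
}
_OTHER_FUNCTION = {"not", "no", "nor", "never", "there", "then", "too", "very",
                   "just", "also", "how", "why", "yes"}

_FUNCTION_WORDS = (
    _DETERMINERS | _PRONOUNS | _PREPOSITIONS | _CONJUNCTIONS | _OTHER_FUNCTION
)

# Irregular verb forms worth recognising beyond suffix rules.
_IRREGULAR_VERBS = {
    "broke": "break", "broken": "break", "went": "go", "gone": "go",
    "got": "get", "gotten": "get", "made": "make", "took": "take",
    "taken": "take", "came": "come", "saw": "see", "seen": "see",
    "gave": "give", "given": "give", "knew": "know", "known": "know",
    "met": "meet", "lost": "lose", "won": "win", "felt": "feel",
    "found": "find", "said": "say", "told": "tell", "thought": "think",
    "kept": "keep", "left": "leave", "grew": "grow", "grown": "grow",
    "fell": "fall", "fallen": "fall", "ran": "run", "wrote": "write",
    "written": "write", "spoke": "speak", "spoken": "speak",
}

_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "al", "ic", "less",
                 "ish", "ary")
_ADVERB_EXCEPTIONS = {"only", "early", "family", "reply", "supply", "ugly",
                      "fly", "apply", "likely"}

_VOWELS = "aeiou"


def _strip_suffix(word: str, suffix: str) -> str:
    return word[: -len(suffix)]


def _undouble(stem: str) -> str:
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS + "ls":
        return stem[:-1]
    return stem


def _lemmatize(word: str, pos: str) -> str:
    """Rule-based lemma keyed on the coarse POS. Lowercase in, lowercase out."""
    if word in _IRREGULAR_VERBS:
        return _IRREGULAR_VERBS[word]
    if pos == "verb":
        if word.endswith("ies") and len(word) > 4:
            return _strip_suffix(word, "ies") + "y"
        if word.endswith("ing") and len(word) > 5:
            stem = _undouble(_strip_suffix(word, "ing"))
            return stem + "e" if _needs_e(stem) else stem
        if word.endswith("ied") and len(word) > 4:
            return _strip_suffix(word, "ied") + "y"
        if word.endswith("ed") and len(word) > 4:
            stem = _undouble(_strip_suffix(word, "ed"))
            return stem + "e" if _needs_e(stem) else stem
        if word.endswith("es") and len(word) > 4 and word[-3] in "sxzh":
            return _strip_suffix(word, "es")
        if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
            return _strip_suffix(word, "s")
    elif pos == "noun":
        if word.endswith("ies") and len(word) > 4:
            return _strip_suffix(word, "ies") + "y"
        if word.endswith("es") and len(word) > 4 and word[-3] in "sxzh":
            return _strip_suffix(word, "es")
        if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
            return _strip_suffix(word, "s")
    elif pos == "adjective":
        if word.endswith("est") and len(word) > 5:
            return _undouble(_strip_suffix(word, "est"))
        if word.endswith("er") and len(word) > 4:
            return _undouble(_strip_suffix(word, "er"))
    return word


def _needs_e(stem: str) -> bool:
    # "hope" -> "hoping": restore the dropped e after C+consonant clusters
    # that would otherwise be unpronounceable stems (heuristic).
    return (
        len(stem) >= 3
        and stem[-1] not in _VOWELS
        and stem[-2] not in _VOWELS
        and stem.endswith(("at", "iv", "us", "as", "os"))
    )


def _tag(word: str, prev: str | None) -> str:
    """Coarse POS for a lowercase word given the previous lowercase token."""
    if not word[0].isalpha():
        return "other"
    if word in _AUXILIARIES:
        return "other"
    if word in _FUNCTION_WORDS:
        return "other"
    if word in _IRREGULAR_VERBS:
        return "verb"
    if word.endswith("ly") and word not in _ADVERB_EXCEPTIONS and len(word) > 3:
        return "adverb"
    if word.endswith(_ADJ_SUFFIXES) and len(word) > 4:
        return "adjective"
    if word.endswith(("ing", "ed")) and len(word) > 4:
        return "verb"
    if prev == "to":
        return "verb"
    if prev in ("will", "would", "can", "could", "shall", "should", "may",
                "might", "must"):
        return "verb"
    return "noun"


def tokenize_sentence(text: str, start_index: int = 0) -> list[Token]:
    """Tokenize one sentence string into tagged :class:`Token` objects."""
    tokens: list[Token] = []
    prev: str | None = None
    for i, match in enumerate(_TOKEN_RE.finditer(text)):
        surface = match.group(0)
        low = surface.lower()
        pos = _tag(low, prev)
        lemma = _lemmatize(low, pos)
        tokens.append(
            Token(
                surface=surface,
                lemma=lemma,
                pos=pos,
                is_content=pos in CONTENT_POS,
                index=start_index + i,
            )
        )
        prev = low
    return tokens


def split_sentences(text: str) -> list[str]:
    """Split text into sentence strings on ., !, ? terminators."""
    out = []
    for para in text.split("\n"):
        para = para.strip()
        if not para:
            continue
        for m in _SENT_RE.finditer(para):
            chunk = m.group(0).strip()
            if chunk:
                out.append(chunk)
    return out


def parse_document(raw: str, doc_id: str) -> Document:
    """Parse raw text into a :class:`Document`.

    Raises :class:`EmptyDocumentError` for empty or whitespace-only input.
    Deterministic: the same bytes always produce the same token stream.
    """
    if not raw or not raw.strip():
        raise EmptyDocumentError(f"document {doc_id!r} is empty")
    sentences = []
    for chunk in split_sentences(raw):
        toks = tokenize_sentence(chunk)
        if toks:
            sentences.append(Sentence(tokens=toks))
    if not sentences:
        raise EmptyDocumentError(f"document {doc_id!r} contains no tokens")
    return Document(doc_id=doc_id, sentences=sentences)


def merge_user_records(records: Sequence[WritingRecord]) -> Document:
    """Merge one user's writing records chronologically into one document.

    Titles, when present, are prepended to their record body; record chunks
    are joined with a sentence terminator so sentence splitting cannot fuse
    text across postings. Invariant to the order records are supplied in.
    """
    if not records:
        raise ValueError("no records supplied")
    user_ids = {r.user_id for r in records}
    if len(user_ids) != 1:
        raise ValueError(f"records mix user_ids: {sorted(user_ids)}")
    ordered = sorted(records, key=lambda r: (r.parsed_timestamp(), r.title, r.body))
    parts = []
    for rec in ordered:
        text = (rec.title.strip() + ". " if rec.title.strip() else "") + rec.body.strip()
        if text and not text.rstrip().endswith((".", "!", "?")):
            text = text.rstrip() + "."
        if text:
            parts.append(text)
    return parse_document(" ".join(parts), doc_id=records[0].user_id)


def read_writing_records(path: str | Path) -> dict[str, list[WritingRecord]]:
    """Read JSON-lines of {user_id, timestamp, title, body} grouped per user."""
    groups: dict[str, list[WritingRecord]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            rec = WritingRecord(
                user_id=obj["user_id"],
                timestamp=obj["timestamp"],
                title=obj.get("title", ""),
                body=obj["body"],
            )
            rec.parsed_timestamp()  # validate eagerly, naming the record
            groups.setdefault(rec.user_id, []).append(rec)
    return groups


def read_labels(path: str | Path) -> LabelTable:
    """Read a label CSV with header ``doc_id,condition,sick``."""
    rows: list[tuple[str, str, bool]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"doc_id", "condition", "sick"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"label file must have header columns {sorted(required)}"
            )
        for row in reader:
            sick_raw = row["sick"].strip().lower()
            if sick_raw not in {"true", "false", "1", "0", "yes", "no"}:
                raise ValueError(f"unreadable sick value {row['sick']!r}")
            rows.append(
                (
                    row["doc_id"].strip(),
                    row["condition"].strip(),
                    sick_raw in {"true", "1", "yes"},
                )
            )
    return LabelTable(rows=rows)


# --------------------------------------------------------------------------
# Stable JSON round trip
# --------------------------------------------------------------------------

def document_to_json(doc: Document) -> str:
    """Serialize a document to the internal JSON form (stable field order)."""
    obj = {
        "doc_id": doc.doc_id,
        "sentences": [
            {
                "tokens": [
                    {
                        "surface": t.surface,
                        "lemma": t.lemma,
                        "pos": t.pos,
                        "index": t.index,
                    }
                    for t in s.tokens
                ],
                "sentiment": (
                    None
                    if s.sentiment is None
                    else {"positive": s.sentiment.positive,
                          "negative": s.sentiment.negative}
                ),
            }
            for s in doc.sentences
        ],
    }
    return json.dumps(obj, ensure_ascii=False, sort_keys=False)


def document_from_json(payload: str) -> Document:
    obj = json.loads(payload)
    sentences = []
    for s in obj["sentences"]:
        toks = [
            Token(
                surface=t["surface"],
                lemma=t["lemma"],
                pos=t["pos"],
                is_content=t["pos"] in CONTENT_POS,
                index=t["index"],
            )
            for t in s["tokens"]
        ]
        sentiment = None
        if s.get("sentiment") is not None:
            sentiment = SentimentScore(
                positive=s["sentiment"]["positive"],
                negative=s["sentiment"]["negative"],
            )
        sentences.append(Sentence(tokens=toks, sentiment=sentiment))
    return Document(doc_id=obj["doc_id"], sentences=sentences)
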