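"""Paired input/output word vectors and the cosine primitive.

Word2vec-style training (CBOW or Skip-Gram) learns two parameter matrices:
the *input* (projection) vectors and the *output* (context / "syn1neg")
vectors. Metaphor identification uses both: the best-fitting sense of a
word in context is chosen by cosine similarity between candidate *input*
vectors and the averaged context vector, while the final sense-difference
score compares *output* vectors of the detected word and its best fit.

Both matrices are stored in the plain word2vec text format (a ``count dim``
header line, then one ``word v1 ... v_dim`` row per word). Most training
tools only export input vectors; the output matrix must be exported
explicitly, hence the two-file convention here. A small in-package
skip-gram negative-sampling trainer is provided for building fixture
stores from tiny corpora.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import Sentence, Token

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingStore",
    "NoContextError",
    "load_store",
    "save_store",
    "cosine",
    "context_vector",
    "train_store",
]


class NoContextError(ValueError):
    """No in-vocabulary context token is available for a detected word."""


@dataclass
class EmbeddingStore:
    """Aligned input and output vector matrices over one vocabulary."""

    words: list[str]
    input_vectors: np.ndarray  # (n_words, dim)
    output_vectors: np.ndarray  # (n_words, dim)
    flavor: str = "skipgram"  # metadata only: {"cbow", "skipgram"}

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.input_vectors.shape != self.output_vectors.shape:
            raise ValueError("input/output matrices must share shape")
        if len(self.words) != self.input_vectors.shape[0]:
            raise ValueError("vocabulary size does not match matrix rows")
        if self.flavor not in ("cbow", "skipgram"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if not (np.isfinite(self.input_vectors).all()
                and np.isfinite(self.output_vectors).all()):
            raise ValueError("vectors must be finite")
        self._index = {w: i for i, w in enumerate(self.words)}

    @property
    def dim(self) -> int:
        return self.input_vectors.shape[1]

    @property
    def vocabulary(self) -> set[str]:
        return set(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def input_vector(self, word: str) -> np.ndarray:
        return self.input_vectors[self._index[word]]

    def output_vector(self, word: str) -> np.ndarray:
        return self.output_vectors[self._index[word]]

    def resolve(self, token: Token) -> str | None:
        """Vocabulary key for a token: lowercase surface, then lemma."""
        for key in (token.surface.lower(), token.lemma.lower()):
            if key in self._index:
                return key
        return None


def _read_w2v_text(path: str | Path) -> tuple[list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: header must be 'count dim'")
        count, dim = int(header[0]), int(header[1])
        words: list[str] = []
        rows = np.empty((count, dim), dtype=np.float64)
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} floats after the word, "
                    f"got {len(parts) - 1}"
                )
            try:
                rows[lineno - 2] = [float(x) for x in parts[1:]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from None
            words.append(parts[0])
        if len(words) != count:
            raise ValueError(f"{path}: header promised {count} rows, got {len(words)}")
    return words, rows


def load_store(
    input_path: str | Path,
    output_path: str | Path,
    *,
    flavor: str = "skipgram",
) -> EmbeddingStore:
    """Load the two word2vec text files and align their vocabularies.

    Words present in only one file are dropped (intersection policy) with a
    logged warning; a dimensionality mismatch is an error.
    """
    in_words, in_mat = _read_w2v_text(input_path)
    out_words, out_mat = _read_w2v_text(output_path)
    if in_mat.shape[1] != out_mat.shape[1]:
        raise ValueError(
            f"dimension mismatch: {input_path} has dim {in_mat.shape[1]}, "
            f"{output_path} has dim {out_mat.shape[1]}"
        )
    out_index = {w: i for i, w in enumerate(out_words)}
    words, in_rows, out_rows = [], [], []
    dropped = []
    for i, w in enumerate(in_words):
        j = out_index.get(w)
        if j is None:
            dropped.append(w)
            continue
        words.append(w)
        in_rows.append(in_mat[i])
        out_rows.append(out_mat[j])
    only_out = set(out_words) - set(in_words)
    if dropped or only_out:
        logger.warning(
            "vocabulary mismatch: %d words only in input file, %d only in "
            "output file; keeping the intersection (%d words)",
            len(dropped), len(only_out), len(words),
        )
    return EmbeddingStore(
        words=words,
        input_vectors=np.asarray(in_rows),
        output_vectors=np.asarray(out_rows),
        flavor=flavor,
    )


def save_store(
    store: EmbeddingStore,
    input_path: str | Path,
    output_path: str | Path,
    *,
    precision: int = 8,
) -> None:
    """Write both matrices in word2vec text format at a fixed precision."""
    for path, mat in ((input_path, store.input_vectors),
                      (output_path, store.output_vectors)):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(store.words)} {store.dim}\n")
            for w, row in zip(store.words, mat):
                vals = " ".join(f"{x:.{precision}g}" for x in row)
                fh.write(f"{w} {vals}\n")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; zero vectors are an error, never 0."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def context_vector(
    sentence: Sentence,
    detected_index: int,
    store: EmbeddingStore,
    *,
    window: int = 0,
) -> np.ndarray:
    """Mean input vector of in-vocabulary context tokens.

    The context is the whole sentence excluding the detected token
    (``window=0``), or a symmetric window of that many tokens on each side.
    Raises :class:`NoContextError` when no context token is in vocabulary.
    """
    toks = sentence.tokens
    if window > 0:
        lo, hi = detected_index - window, detected_index + window
        toks = [t for t in toks if lo <= t.index <= hi]
    vecs = []
    for tok in toks:
        if tok.index == detected_index:
            continue
        key = store.resolve(tok)
        if key is not None:
            vecs.append(store.input_vector(key))
    if not vecs:
        raise NoContextError(
            f"no in-vocabulary context for token index {detected_index}"
        )
    return np.mean(vecs, axis=0)


# --------------------------------------------------------------------------
# Tiny skip-gram negative-sampling trainer (fixture-scale corpora only)
# --------------------------------------------------------------------------

def train_store(
    sentences: list[list[str]],
    *,
    dim: int = 16,
    window: int = 2,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.025,
    min_count: int = 1,
    seed: int = 0,
) -> EmbeddingStore:
    """Train both matrices by skip-gram with negative sampling.

    Intended for building small fixture stores from toy corpora; it is a
    plain SGD loop with no threading or vocabulary subsampling and does not
    scale to large corpora.
    """
    counts: dict[str, int] = {}
    for sent in sentences:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("empty vocabulary after min_count filtering")
    index = {w: i for i, w in enumerate(vocab)}
    n = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((n, dim)) - 0.5) / dim
    W_out = np.zeros((n, dim))

    freqs = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    noise_p = freqs / freqs.sum()

    ids_sents = [
        [index[w] for w in sent if w in index] for sent in sentences
    ]
    for _epoch in range(epochs):
        for ids in ids_sents:
            for pos, center in enumerate(ids):
                lo = max(0, pos - window)
                hi = min(len(ids), pos + window + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    target = ids[ctx_pos]
                    negs = rng.choice(n, size=negative, p=noise_p)
                    samples = [(target, 1.0)] + [(t, 0.0) for t in negs]
                    v = W_in[center]
                    grad_v = np.zeros(dim)
                    for t, label in samples:
                        u = W_out[t]
                        score = 1.0 / (1.0 + math.exp(-float(np.dot(v, u))))
                        g = lr * (label - score)
                        grad_v += g * u
                        W_out[t] += g * v
                    W_in[center] += grad_v
    return EmbeddingStore(
        words=vocab,
        input_vectors=W_in,
        output_vectors=W_out,
        flavor="skipgram",
    )
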