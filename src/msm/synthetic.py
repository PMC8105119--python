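"""Synthetic study inputs: planted embeddings, lexicons, and cohorts.

Everything the pipeline consumes can be generated here at fixture scale,
fully determined by a seed:

* :func:`make_embeddings` builds an embedding store with *planted* metaphor
  geometry. Four orthonormal directions are drawn: ``a`` (the topic/context
  direction), ``b`` (the input direction of detected words), and an output
  plane ``(e, f)``. Every detected pseudoword ``w`` is wired in the ontology
  to a synonym ``syn_w`` (input vector ``a``, so it wins the best-fit argmax
  whenever topic words dominate the context) and a hypernym (input ``-a``).
  Output vectors place metaphorical words at cosine ``(0.5 - margin) / 2``
  from their synonym — below the 0.5 decision threshold by more than the
  margin — and literal words at ``(1.5 + margin) / 2``, symmetrically above
  it. The geometry is re-verified by direct cosine computation at
  generation time.
* :func:`make_lexicons` emits a strength lexicon (pseudowords carrying each
  positive/negative strength level), a sentic lexicon, and the ontology
  wiring, all over the planted vocabulary.
* :func:`make_planted_corpus` produces single-detected-word template
  sentences with exact gold labels for identifier evaluation.
* :func:`make_cohort` produces a two-class document cohort in which the
  sick and healthy groups differ in their metaphor rate (probability that a
  content slot hosts a planted metaphorical word) and their mean sentence
  sentiment. Sentence text is template-based: the pipeline consumes token
  streams, so linguistic realism is not required for correctness testing.

Pseudoword suffixes use only letters that trigger no tagger or lemmatizer
rule, so every generated word is tagged as a noun and survives
lemmatization unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import Document, LabelTable, parse_document
from .embeddings import EmbeddingStore, cosine, save_store
from .lexicons import Ontology, SenticEntry, SenticLexicon, StrengthLexicon

__all__ = [
    "PlantedEmbeddingSpec",
    "PlantedWorld",
    "CohortSpec",
    "Cohort",
    "LexiconSet",
    "CONDITION_PREVALENCE",
    "make_embeddings",
    "make_lexicons",
    "make_planted_corpus",
    "make_cohort",
]

# Students per condition out of a cohort of 156 (study-scale prevalences).
CONDITION_PREVALENCE = {
    "anxiety": 36 / 156,
    "depression": 36 / 156,
    "inferiority": 29 / 156,
    "sensitivity": 49 / 156,
    "social_phobia": 44 / 156,
    "obsession": 38 / 156,
}

# Suffix alphabet chosen so no tagger/lemmatizer suffix rule can fire.
_SAFE = "bfghjkm"


def _pseudowords(prefix: str, n: int) -> list[str]:
    out = []
    for i in range(n):
        hi, lo = divmod(i, len(_SAFE))
        if hi >= len(_SAFE):
            raise ValueError(f"too many {prefix!r} words requested ({n})")
        out.append(prefix + _SAFE[hi] + _SAFE[lo])
    return out


@dataclass
class PlantedEmbeddingSpec:
    n_metaphor: int = 10
    n_literal: int = 10
    n_topic: int = 6
    dim: int = 8
    margin: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.margin < 0.5:
            raise ValueError("margin must lie in (0, 0.5)")
        if self.dim < 4:
            raise ValueError(
                "planted geometry needs dim >= 4 (four orthonormal directions)"
            )


@dataclass
class PlantedWorld:
    """A planted embedding store with its ontology and ground truth."""

    spec: PlantedEmbeddingSpec
    store: EmbeddingStore
    ontology: Ontology
    truth: dict[str, str]  # detected word -> metaphorical | literal
    metaphor_words: list[str]
    literal_words: list[str]
    topic_words: list[str]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_store(
            self.store,
            out_dir / "embeddings_input.txt",
            out_dir / "embeddings_output.txt",
        )
        with open(out_dir / "ontology.json", "w", encoding="utf-8") as fh:
            json.dump(self.ontology.entries, fh, indent=1, sort_keys=True)
        with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def make_embeddings(spec: PlantedEmbeddingSpec) -> PlantedWorld:
    """Construct the planted store; verify the geometry before returning."""
    rng = np.random.default_rng(spec.seed)
    basis, _ = np.linalg.qr(rng.normal(size=(spec.dim, spec.dim)))
    a, b, e, f = basis[:, 0], basis[:, 1], basis[:, 2], basis[:, 3]

    met = _pseudowords("met", spec.n_metaphor)
    lit = _pseudowords("lit", spec.n_literal)
    top = _pseudowords("top", spec.n_topic)
    syn = {w: "syn" + w for w in met + lit}
    hyp = {w: "hyp" + w for w in met + lit}

    cos_met = (0.5 - spec.margin) / 2.0
    cos_lit = (1.5 + spec.margin) / 2.0

    words: list[str] = []
    in_rows: list[np.ndarray] = []
    out_rows: list[np.ndarray] = []

    def _add(word: str, vin: np.ndarray, vout: np.ndarray) -> None:
        words.append(word)
        in_rows.append(vin)
        out_rows.append(vout)

    for w in top:
        _add(w, a, e)
    for w, c in [(w, cos_met) for w in met] + [(w, cos_lit) for w in lit]:
        vout = c * e + np.sqrt(1.0 - c * c) * f
        _add(w, b, vout)
        _add(syn[w], a, e)
        _add(hyp[w], -a, f)

    store = EmbeddingStore(
        words=words,
        input_vectors=np.asarray(in_rows),
        output_vectors=np.asarray(out_rows),
    )
    ontology = Ontology(
        entries={
            w: {"noun": {"synonyms": [syn[w]], "hypernyms": [hyp[w]]}}
            for w in met + lit
        }
    )
    truth = {w: "metaphorical" for w in met}
    truth.update({w: "literal" for w in lit})
    truth.update({w: "literal" for w in top})

    # self-check: planted output cosines must clear the margin band
    lo, hi = 0.5 - spec.margin, 0.5 + spec.margin
    for w in met + lit:
        c = cosine(store.output_vector(w), store.output_vector(syn[w]))
        if lo < c < hi:
            raise AssertionError(
                f"planted geometry violated for {w!r}: cosine {c:.3f} "
                f"inside ({lo:.2f}, {hi:.2f})"
            )
        if (truth[w] == "metaphorical") != (c < 0.5):
            raise AssertionError(f"planted label inconsistent for {w!r}")

    return PlantedWorld(
        spec=spec,
        store=store,
        ontology=ontology,
        truth=truth,
        metaphor_words=met,
        literal_words=lit,
        topic_words=top,
    )


# --------------------------------------------------------------------------
# Lexicons over the planted vocabulary
# --------------------------------------------------------------------------

@dataclass
class LexiconSet:
    strength: StrengthLexicon
    sentic: SenticLexicon
    # strength level (2..5) -> pseudoword carrying that level
    positive_words: dict[int, str]
    negative_words: dict[int, str]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "strength_lexicon.csv", "w", encoding="utf-8") as fh:
            fh.write("word,pos_strength,neg_strength\n")
            for w, (p, n) in sorted(self.strength.entries.items()):
                fh.write(f"{w},{p},{n}\n")
        with open(out_dir / "sentic_lexicon.csv", "w", encoding="utf-8") as fh:
            fh.write("word,pleasantness,attention,sensitivity,aptitude,polarity\n")
            for w, entry in sorted(self.sentic.entries.items()):
                vals = ",".join(f"{v:.4f}" for v in entry.values())
                fh.write(f"{w},{vals}\n")


def make_lexicons(world: PlantedWorld, seed: int | None = None) -> LexiconSet:
    """Strength and sentic lexicons covering the planted vocabulary.

    One dedicated pseudoword per positive strength level 2..5 and per
    negative level -2..-5, so cohort generation can realise any target
    sentence score exactly. Sentic values are seeded draws in [-1, 1],
    with pleasantness and polarity aligned to the sign of sentiment words.
    """
    rng = np.random.default_rng(world.spec.seed if seed is None else seed)
    strength = StrengthLexicon()
    positive_words = {}
    negative_words = {}
    pos_names = _pseudowords("posw", 4)
    neg_names = _pseudowords("negw", 4)
    for level, word in zip(range(2, 6), pos_names):
        strength.add(word, level, -1)
        positive_words[level] = word
    for level, word in zip(range(2, 6), neg_names):
        strength.add(word, 1, -level)
        negative_words[level] = word

    sentic = SenticLexicon()

    def _entry(word: str, sign: float) -> SenticEntry:
        base = rng.uniform(-0.2, 0.2, size=5)
        if sign != 0.0:
            base[0] = sign * rng.uniform(0.4, 0.9)  # pleasantness
            base[4] = sign * rng.uniform(0.4, 0.9)  # polarity
        return SenticEntry(word, *np.clip(base, -1.0, 1.0))

    for word in pos_names:
        sentic.add(_entry(word, 1.0))
    for word in neg_names:
        sentic.add(_entry(word, -1.0))
    for word in world.topic_words + world.metaphor_words + world.literal_words:
        sentic.add(_entry(word, 0.0))

    return LexiconSet(
        strength=strength,
        sentic=sentic,
        positive_words=positive_words,
        negative_words=negative_words,
    )


# --------------------------------------------------------------------------
# Template corpora
# --------------------------------------------------------------------------

def make_planted_corpus(
    world: PlantedWorld,
    sentences_per_word: int = 3,
    seed: int = 0,
) -> tuple[list[Document], dict[tuple[str, int, int], str]]:
    """Single-detected-word sentences with exact gold token labels.

    Each sentence embeds one planted word between two topic words, so the
    context vector is exactly the topic direction and the identifier's
    decision is fully determined by the planted output geometry.
    """
    rng = np.random.default_rng(seed)
    detected = world.metaphor_words + world.literal_words
    lines = []
    for w in detected:
        for _ in range(sentences_per_word):
            t1, t2 = rng.choice(world.topic_words, size=2, replace=True)
            lines.append(f"The {t1} was a {w} of the {t2}.")
    doc = parse_document(" ".join(lines), doc_id="planted")
    gold: dict[tuple[str, int, int], str] = {}
    for si, sent in enumerate(doc.sentences):
        for tok in sent.content_tokens():
            label = world.truth.get(tok.surface.lower(), "literal")
            gold[(doc.doc_id, si, tok.index)] = label
    return [doc], gold


@dataclass
class CohortSpec:
    """Two-class cohort with controlled metaphor and sentiment effects.

    ``metaphor_rate_*`` is the probability that a content slot hosts a
    planted metaphorical word; ``mean_sentiment_*`` is the target mean of
    the per-sentence overall sentiment score (integer scale -4..4).
    Defaults mirror a study-scale binary task: 36 sick vs 120 healthy
    authors, a strong metaphor-rate contrast (0.10 vs 0.02), and opposite
    mean sentiment (-1 vs +1).
    """

    n_sick: int = 36
    n_healthy: int = 120
    metaphor_rate_sick: float = 0.10
    metaphor_rate_healthy: float = 0.02
    mean_sentiment_sick: float = -1.0
    mean_sentiment_healthy: float = 1.0
    sentiment_sd: float = 1.2
    sentences_per_doc: tuple[int, int] = (10, 16)
    slots_per_sentence: tuple[int, int] = (5, 9)
    condition: str = "depression"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.metaphor_rate_sick, self.metaphor_rate_healthy):
            if not 0.0 <= r <= 1.0:
                raise ValueError("metaphor rates must lie in [0, 1]")
        if min(self.n_sick, self.n_healthy) < 1:
            raise ValueError("both groups need at least one document")


@dataclass
class Cohort:
    documents: list[Document]
    labels: LabelTable
    # per-document realized generation record:
    #   {"sick": bool, "n_slots": int, "n_metaphor_slots": int,
    #    "sentence_scores": [int, ...]}
    truth: dict[str, dict]
    spec: CohortSpec


def _target_scores(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    return np.clip(np.rint(rng.normal(mean, sd, size=n)), -4, 4).astype(int)


def make_cohort(
    spec: CohortSpec,
    world: PlantedWorld,
    lexicons: LexiconSet,
) -> Cohort:
    """Generate the two-class cohort over the planted vocabulary.

    Each sentence fills its content slots independently: a planted
    metaphorical word with the class's metaphor rate, otherwise a topic
    word (three times out of four) or a planted literal word. One strength
    pseudoword realises the sentence's target sentiment score exactly;
    topic words keep the context direction dominant so the identifier
    recovers the planted labels.
    """
    rng = np.random.default_rng(spec.seed)
    documents: list[Document] = []
    rows: list[tuple[str, str, bool]] = []
    truth: dict[str, dict] = {}

    groups = [(True, spec.n_sick, spec.metaphor_rate_sick, spec.mean_sentiment_sick),
              (False, spec.n_healthy, spec.metaphor_rate_healthy,
               spec.mean_sentiment_healthy)]
    for sick, n_docs, rate, mean in groups:
        for d in range(n_docs):
            doc_id = f"{'sick' if sick else 'ctrl'}{d:04d}"
            n_sent = int(rng.integers(spec.sentences_per_doc[0],
                                      spec.sentences_per_doc[1] + 1))
            scores = _target_scores(rng, n_sent, mean, spec.sentiment_sd)
            n_slots = n_met = 0
            lines = []
            for s in scores:
                k = int(rng.integers(spec.slots_per_sentence[0],
                                     spec.slots_per_sentence[1] + 1))
                slot_words = []
                for _ in range(k):
                    n_slots += 1
                    if rng.random() < rate:
                        n_met += 1
                        slot_words.append(str(rng.choice(world.metaphor_words)))
                    elif rng.random() < 0.75:
                        slot_words.append(str(rng.choice(world.topic_words)))
                    else:
                        slot_words.append(str(rng.choice(world.literal_words)))
                if s > 0:
                    slot_words.append(lexicons.positive_words[min(5, s + 1)])
                elif s < 0:
                    slot_words.append(lexicons.negative_words[min(5, 1 - s)])
                lines.append("The " + " ".join(slot_words) + ".")
            documents.append(parse_document(" ".join(lines), doc_id=doc_id))
            rows.append((doc_id, spec.condition, sick))
            truth[doc_id] = {
                "sick": sick,
                "n_slots": n_slots,
                "n_metaphor_slots": n_met,
                "sentence_scores": [int(s) for s in scores],
            }
    return Cohort(
        documents=documents,
        labels=LabelTable(rows=rows),
        truth=truth,
        spec=spec,
    )
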