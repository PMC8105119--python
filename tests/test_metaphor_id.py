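import numpy as np
import pytest

from msm.corpus_io import Sentence, Token
from msm.embeddings import EmbeddingStore
from msm.lexicons import Ontology
from msm.metaphor_id import (
    EvalReport,
    annotate_document,
    best_fit,
    decide,
    evaluate,
)
from msm.lexicons import candidate_set


def _token(word, index=0):
    return Token(surface=word, lemma=word, pos="noun", is_content=True,
                 index=index)


def _sentence(words):
    return Sentence(tokens=[_token(w, i) for i, w in enumerate(words)])


def _store(vectors, out_vectors=None):
    words = sorted(vectors)
    inp = np.array([vectors[w] for w in words], dtype=float)
    out = (inp.copy() if out_vectors is None
           else np.array([out_vectors[w] for w in words], dtype=float))
    return EmbeddingStore(words=words, input_vectors=inp, output_vectors=out)


class TestBestFit:
    def test_singleton_candidates(self):
        store = _store({"fox": [1.0, 0.0], "den": [0.0, 1.0]})
        sent = _sentence(["fox", "den"])
        cands = candidate_set(sent.tokens[0], Ontology())
        word, _ = best_fit(sent.tokens[0], sent, store, cands)
        assert word == "fox"

    def test_argmax_matches_enumeration(self):
        store = _store(
            {
                "fox": [1.0, 0.0],
                "wolf": [0.8, 0.6],
                "animal": [0.0, 1.0],
                "den": [0.1, 0.9],
            }
        )
        onto = Ontology(entries={"fox": {"noun": {"synonyms": ["wolf"],
                                                  "hypernyms": ["animal"]}}})
        sent = _sentence(["fox", "den"])
        cands = candidate_set(sent.tokens[0], onto)
        word, sim = best_fit(sent.tokens[0], sent, store, cands)
        # context is "den" = (0.1, 0.9); enumerate candidates by hand:
        # fox ~ 0.110, wolf ~ 0.685, animal ~ 0.994 -> animal wins
        assert word == "animal"
        assert sim == pytest.approx(0.9 / np.sqrt(0.1**2 + 0.9**2), abs=1e-9)

    def test_tie_breaks_lexicographically(self):
        store = _store(
            {"apple": [1.0, 0.0], "berry": [1.0, 0.0], "ctx": [1.0, 0.0]}
        )
        onto = Ontology(entries={"apple": {"noun": {"synonyms": ["berry"],
                                                    "hypernyms": []}}})
        sent = _sentence(["apple", "ctx"])
        cands = candidate_set(sent.tokens[0], onto)
        word, _ = best_fit(sent.tokens[0], sent, store, cands)
        assert word == "apple"  # equal cosines; lexicographic winner


class TestDecide:
    def test_self_best_fit_is_literal(self):
        store = _store({"fox": [1.0, 0.0], "den": [0.0, 1.0]})
        sent = _sentence(["fox", "den"])
        dec = decide(sent.tokens[0], sent, store, Ontology(), threshold=1.0)
        assert dec.best_fit == "fox"
        assert dec.sim_detected_bestfit == pytest.approx(1.0)
        assert dec.label == "literal"

    def test_impossible_threshold_all_literal(self):
        store = _store(
            {"fox": [1.0, 0.0], "wolf": [0.0, 1.0], "den": [0.0, 1.0]},
            out_vectors={"fox": [1.0, 0.0], "wolf": [0.0, 1.0],
                         "den": [1.0, 1.0]},
        )
        onto = Ontology(entries={"fox": {"noun": {"synonyms": ["wolf"],
                                                  "hypernyms": []}}})
        sent = _sentence(["fox", "den"])
        dec = decide(sent.tokens[0], sent, store, onto, threshold=-1.0)
        assert dec.label == "literal"

    def test_orthogonal_output_vectors_flag_metaphor(self):
        # best fit is "wolf" (input matches context); its output vector is
        # orthogonal to the detected word's -> cosine 0 < 0.5
        store = _store(
            {"fox": [1.0, 0.0], "wolf": [0.0, 1.0], "den": [0.0, 1.0]},
            out_vectors={"fox": [1.0, 0.0], "wolf": [0.0, 1.0],
                         "den": [1.0, 1.0]},
        )
        onto = Ontology(entries={"fox": {"noun": {"synonyms": ["wolf"],
                                                  "hypernyms": []}}})
        sent = _sentence(["fox", "den"])
        dec = decide(sent.tokens[0], sent, store, onto, threshold=0.5)
        assert dec.best_fit == "wolf"
        assert dec.sim_detected_bestfit == pytest.approx(0.0)
        assert dec.label == "metaphorical"

    def test_oov_detected_is_skipped(self):
        store = _store({"den": [1.0, 0.0], "sky": [0.0, 1.0]})
        sent = _sentence(["fox", "den"])
        dec = decide(sent.tokens[0], sent, store, Ontology())
        assert dec.label == "skipped"
        assert "vocabulary" in dec.skip_reason

    def test_no_context_is_skipped(self):
        store = _store({"fox": [1.0, 0.0]})
        sent = _sentence(["fox", "qqq"])
        dec = decide(sent.tokens[0], sent, store, Ontology())
        assert dec.label == "skipped"
        assert "context" in dec.skip_reason


class TestAnnotate:
    def test_planted_token_recovered(self, world, planted_corpus):
        docs, gold = planted_corpus
        for doc in docs:
            annotate_document(doc, world.store, world.ontology)
        rep = evaluate(gold, docs)
        assert rep.f1 == 1.0

    def test_idempotent(self, world, planted_corpus):
        docs, _ = planted_corpus
        doc = docs[0]
        annotate_document(doc, world.store, world.ontology)
        first = [
            (ti, d.label)
            for s in doc.sentences
            for ti, d in sorted(s.metaphor.items())
        ]
        annotate_document(doc, world.store, world.ontology)
        second = [
            (ti, d.label)
            for s in doc.sentences
            for ti, d in sorted(s.metaphor.items())
        ]
        assert first == second

    def test_no_content_words_no_decisions(self, world):
        from msm.corpus_io import parse_document

        doc = parse_document("Of the in.", "fn")
        annotate_document(doc, world.store, world.ontology)
        assert all(len(s.metaphor) == 0 for s in doc.sentences)

    def test_threshold_monotonicity(self, world, planted_corpus):
        docs, _ = planted_corpus
        previous: set | None = None
        for threshold in np.linspace(-1.0, 1.0, 10):
            for doc in docs:
                annotate_document(doc, world.store, world.ontology,
                                  float(threshold))
            flagged = {
                (doc.doc_id, si, ti)
                for doc in docs
                for si, s in enumerate(doc.sentences)
                for ti, d in s.metaphor.items()
                if d.is_metaphorical
            }
            if previous is not None:
                assert previous <= flagged
            previous = flagged


class TestEvaluate:
    def _docs_with_labels(self, labels):
        from msm.corpus_io import Document

        sent = _sentence([f"w{i}" for i in range(len(labels))])
        doc = Document(doc_id="e", sentences=[sent])
        decisions = {}
        for i, lab in enumerate(labels):
            decisions[i] = type(
                "D", (), {"is_metaphorical": lab == "metaphorical"}
            )()
        sent.metaphor = decisions
        return [doc]

    def test_perfect_prediction(self):
        gold = {("e", 0, i): "metaphorical" if i < 2 else "literal"
                for i in range(4)}
        docs = self._docs_with_labels(
            ["metaphorical", "metaphorical", "literal", "literal"]
        )
        rep = evaluate(gold, docs)
        assert (rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0)

    def test_all_literal_prediction(self):
        gold = {("e", 0, 0): "metaphorical", ("e", 0, 1): "literal"}
        docs = self._docs_with_labels(["literal", "literal"])
        rep = evaluate(gold, docs)
        assert rep.recall == 0.0 and rep.f1 == 0.0

    def test_hand_counted_confusion(self):
        # 10 tokens: 2 TP, 1 FP, 1 FN, 6 TN -> P = R = F1 = 2/3
        gold_labels = ["metaphorical"] * 3 + ["literal"] * 7
        pred_labels = (["metaphorical", "metaphorical", "literal"]
                       + ["metaphorical"] + ["literal"] * 6)
        gold = {("e", 0, i): lab for i, lab in enumerate(gold_labels)}
        docs = self._docs_with_labels(pred_labels)
        rep = evaluate(gold, docs)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (2, 1, 1, 6)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_unmatched_ids_error(self):
        gold = {("other", 0, 0): "literal"}
        docs = self._docs_with_labels(["literal"])
        with pytest.raises(ValueError, match="other"):
            evaluate(gold, docs)


def test_f1_definition_edge():
    assert EvalReport(tp=0, fp=0, tn=5, fn=0).f1 == 0.0
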