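import numpy as np
import pandas as pd
import pytest

from msm.corpus_io import Document, LabelTable, Sentence, SentimentScore, Token
from msm.features import (
    FEATURE_ORDER,
    MetaphorSentimentFeaturizer,
    build_matrix,
    frequent_metaphors,
    group_compare,
    metaphor_features,
    sentiment_features,
    subset_columns,
)
from msm.lexicons import SenticEntry, SenticLexicon


class _Dec:
    def __init__(self, metaphorical, lemma="w"):
        self.is_metaphorical = metaphorical
        self.detected = lemma


def _tok(word, i):
    return Token(surface=word, lemma=word, pos="noun", is_content=True, index=i)


def _score(overall):
    """A SentimentScore pair realising the given overall score exactly."""
    if overall >= 0:
        return SentimentScore(positive=overall + 1, negative=-1)
    return SentimentScore(positive=1, negative=overall - 1)


def _doc(sentence_specs, doc_id="d"):
    """sentence_specs: list of (words, overall_score, metaphor_indices)."""
    sentences = []
    for words, overall, meta_idx in sentence_specs:
        sent = Sentence(tokens=[_tok(w, i) for i, w in enumerate(words)])
        sent.sentiment = _score(overall)
        sent.metaphor = {
            i: _Dec(i in meta_idx, lemma=words[i]) for i in range(len(words))
        }
        sentences.append(sent)
    return Document(doc_id=doc_id, sentences=sentences)


class TestMetaphorFeatures:
    def test_no_metaphors_all_zero(self):
        doc = _doc([(["a", "b"], 2, set()), (["c"], 0, set())])
        f = metaphor_features(doc)
        assert f.as_tuple() == (0.0, 0.0, 0, 0, 0.0)

    def test_hand_counted_fixture(self):
        # 10 tokens over 3 sentences; 2 metaphors in a +2 sentence, 1 in a
        # -1 sentence -> pct 0.3, prob 2/3, n_pos 2, n_neg 1,
        # avg (2 + 2 - 1)/3 = 1.0
        doc = _doc(
            [
                (["a", "b", "c", "d"], 2, {0, 1}),
                (["e", "f", "g"], -1, {2}),
                (["h", "i", "j"], 3, set()),
            ]
        )
        f = metaphor_features(doc)
        assert f.pct_metaphor_tokens == pytest.approx(0.3)
        assert f.prob_sentence_with_metaphor == pytest.approx(2 / 3)
        assert (f.n_pos_metaphor, f.n_neg_metaphor) == (2, 1)
        assert f.avg_metaphor_sentiment == pytest.approx(1.0)

    def test_neutral_sentences_feed_neither_count(self):
        doc = _doc([(["a", "b"], 0, {0, 1}), (["c", "d"], 0, {0, 1})])
        f = metaphor_features(doc)
        assert (f.n_pos_metaphor, f.n_neg_metaphor) == (0, 0)
        assert f.avg_metaphor_sentiment == 0.0

    def test_inherited_score_bounded_by_sentence_range(self, rng):
        for _ in range(20):
            specs = []
            for _s in range(int(rng.integers(2, 6))):
                words = [f"w{i}" for i in range(int(rng.integers(1, 5)))]
                overall = int(rng.integers(-4, 5))
                meta = {int(i) for i in
                        rng.choice(len(words),
                                   size=int(rng.integers(0, len(words) + 1)),
                                   replace=False)}
                specs.append((words, overall, meta))
            doc = _doc(specs)
            scores_with = [s for w, s, m in specs if m]
            f = metaphor_features(doc)
            if scores_with:
                assert min(scores_with) <= f.avg_metaphor_sentiment <= max(
                    scores_with
                )

    def test_unannotated_document_rejected(self):
        sent = Sentence(tokens=[_tok("a", 0)])
        sent.sentiment = _score(0)
        doc = Document(doc_id="u", sentences=[sent])
        with pytest.raises(ValueError, match="not metaphor-annotated"):
            metaphor_features(doc)


SENTIC = SenticLexicon()
for word, vals in {
    "hope": (0.8, 0.2, -0.1, 0.5, 0.7),
    "fear": (-0.7, 0.4, 0.6, -0.3, -0.8),
    "road": (0.1, 0.0, 0.0, 0.2, 0.1),
}.items():
    SENTIC.add(SenticEntry(word, *vals))


class TestSentimentFeatures:
    def test_average_and_fluctuation_formulas(self):
        doc = _doc([(["a"], 2, set()), (["b"], -3, set()), (["c"], 1, set())])
        f = sentiment_features(doc, SENTIC)
        assert f.avg_sentence_sentiment == pytest.approx(0.0)
        assert f.fluctuation == pytest.approx(4.5)  # (|−3−2| + |1+3|)/2

    def test_constant_scores(self):
        doc = _doc([(["a"], 1, set())] * 3)
        f = sentiment_features(doc, SENTIC)
        assert f.fluctuation == 0.0
        assert f.frac_pos_sentences == 1.0

    def test_single_sentence_fluctuation_zero(self):
        doc = _doc([(["a"], 3, set())])
        assert sentiment_features(doc, SENTIC).fluctuation == 0.0

    def test_fractions_sum_to_one(self):
        doc = _doc([(["a"], 2, set()), (["b"], -1, set()), (["c"], 0, set())])
        f = sentiment_features(doc, SENTIC)
        total = (f.frac_pos_sentences + f.frac_neg_sentences
                 + f.frac_neutral_sentences)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert (f.frac_pos_sentences, f.frac_neg_sentences) == (
            pytest.approx(1 / 3), pytest.approx(1 / 3))

    def test_sentic_means_hand_computed(self):
        # 6 matched tokens: hope x2, fear x3, road x1
        doc = _doc(
            [
                (["hope", "fear", "road"], 0, set()),
                (["fear", "hope", "fear", "zzz"], 0, set()),
            ]
        )
        f = sentiment_features(doc, SENTIC)
        expected = (
            2 * np.array((0.8, 0.2, -0.1, 0.5, 0.7))
            + 3 * np.array((-0.7, 0.4, 0.6, -0.3, -0.8))
            + np.array((0.1, 0.0, 0.0, 0.2, 0.1))
        ) / 6
        got = (f.mean_pleasantness, f.mean_attention, f.mean_sensitivity,
               f.mean_aptitude, f.mean_polarity)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_no_sentic_hits_zero_means(self):
        doc = _doc([(["qqq"], 2, set())])
        f = sentiment_features(doc, SENTIC)
        assert (f.mean_pleasantness, f.mean_polarity) == (0.0, 0.0)

    def test_translation_covariance_of_average(self):
        scores = [2, -3, 1, 0]
        base = _doc([([f"w{i}"], s, set()) for i, s in enumerate(scores)])
        shifted = _doc([([f"w{i}"], s + 1, set())
                        for i, s in enumerate(scores)])
        f0 = sentiment_features(base, SENTIC)
        f1 = sentiment_features(shifted, SENTIC)
        assert f1.avg_sentence_sentiment == pytest.approx(
            f0.avg_sentence_sentiment + 1
        )
        assert f1.fluctuation == pytest.approx(f0.fluctuation)

    def test_fluctuation_is_order_sensitive(self):
        a = _doc([([f"w{i}"], s, set()) for i, s in enumerate([2, -3, 1])])
        b = _doc([([f"w{i}"], s, set()) for i, s in enumerate([-3, 1, 2])])
        fa, fb = sentiment_features(a, SENTIC), sentiment_features(b, SENTIC)
        assert fa.fluctuation != fb.fluctuation
        assert fa.avg_sentence_sentiment == fb.avg_sentence_sentiment


class TestMatrix:
    def _docs(self, n=4):
        return [
            _doc([(["hope", "road"], 1, {0}), (["fear"], -2, set())],
                 doc_id=f"d{i}")
            for i in range(n)
        ]

    def _labels(self, n=4):
        rows = [(f"d{i}", "depression", i % 2 == 0) for i in range(n)]
        return LabelTable(rows=rows)

    def test_full_matrix_shape_and_order(self):
        X, y = build_matrix(self._docs(), self._labels(), "depression", SENTIC)
        assert X.shape == (4, 15)
        assert tuple(X.columns) == FEATURE_ORDER
        assert y.tolist() == [True, False, True, False]

    def test_meta_subset(self):
        X, _ = build_matrix(self._docs(), self._labels(), "depression",
                            SENTIC, feature_set="meta")
        assert X.shape == (4, 5)
        from msm.features import METAPHOR_FEATURES

        assert tuple(X.columns) == METAPHOR_FEATURES

    def test_missing_label_named(self):
        labels = LabelTable(rows=[("d0", "depression", True)])
        with pytest.raises(ValueError, match="d1"):
            build_matrix(self._docs(), labels, "depression", SENTIC)

    def test_deterministic_csv(self, tmp_path):
        frames = []
        for _ in range(2):
            X, _ = build_matrix(self._docs(), self._labels(), "depression",
                                SENTIC)
            p = tmp_path / "f.csv"
            X.to_csv(p)
            frames.append(p.read_bytes())
        assert frames[0] == frames[1]

    def test_totality_on_cohort(self, annotated_cohort):
        _, X, _ = annotated_cohort
        assert np.isfinite(X.to_numpy()).all()
        assert X.shape[1] == 15


class TestGroupCompare:
    def test_identical_groups_t_zero(self):
        data = np.tile(np.array([[0.0], [1.0], [2.0], [3.0]]), (2, 1))
        X = pd.DataFrame(data, columns=["f"])
        y = np.array([True] * 4 + [False] * 4)
        stats = group_compare(X, y)
        assert stats.loc["f", "t"] == pytest.approx(0.0, abs=1e-12)

    def test_shift_recovered_within_three_se(self, rng):
        n = 200
        a = rng.normal(1.0, 1.0, size=n)
        b = rng.normal(0.0, 1.0, size=n)
        X = pd.DataFrame({"f": np.concatenate([a, b])})
        y = np.array([True] * n + [False] * n)
        stats = group_compare(X, y)
        diff = stats.loc["f", "mean_sick"] - stats.loc["f", "mean_not_sick"]
        se = np.sqrt(a.var(ddof=1) / n + b.var(ddof=1) / n)
        assert abs(diff - 1.0) < 3 * se

    def test_sign_convention(self):
        X = pd.DataFrame({"f": [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]})
        y = np.array([True] * 3 + [False] * 3)
        stats = group_compare(X, y)
        assert stats.loc["f", "t"] > 0

    def test_small_group_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="at least 2"):
            group_compare(X, np.array([True, False, False]))


class TestFrequentMetaphors:
    def _group(self, word_counts, doc_id="g"):
        specs = []
        for word, count in word_counts.items():
            for _ in range(count):
                specs.append(([word], 0, {0}))
        return [_doc(specs, doc_id=doc_id)]

    def test_plain_ranking(self):
        groups = {"a": self._group({"pay": 5, "top": 3, "dream": 1})}
        out = frequent_metaphors(groups, top_k=3, global_exclude_k=0)
        assert out["a"] == [("pay", 5), ("top", 3), ("dream", 1)]

    def test_global_exclusion(self):
        groups = {
            "a": self._group({"pay": 5, "dream": 2}, "ga"),
            "b": self._group({"pay": 4, "chase": 3}, "gb"),
        }
        out = frequent_metaphors(groups, top_k=5, global_exclude_k=1)
        assert all("pay" not in dict(v) for v in out.values())
        assert out["b"][0] == ("chase", 3)

    def test_hand_counted_ranking(self):
        groups = {"a": self._group({"meet": 4, "hit": 2, "clean": 2})}
        out = frequent_metaphors(groups, top_k=10)
        assert out["a"] == [("meet", 4), ("clean", 2), ("hit", 2)]

    def test_empty_group(self):
        assert frequent_metaphors({"a": []})["a"] == []


def test_subset_columns_rejects_unknown():
    X = pd.DataFrame(columns=list(FEATURE_ORDER))
    with pytest.raises(ValueError):
        subset_columns(X, "bogus")
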