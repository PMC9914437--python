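"""Signal-to-text encoding: tokens, vocabulary, counts, TF-IDF."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from audeeg.epochs import Epoch, LabeledEvent
from audeeg.features import (
    GridError,
    TokenDocument,
    Vocabulary,
    build_vocabulary,
    count_vectorize,
    counts_from_epochs,
    document_frequency,
    fit_feature_matrix,
    idf,
    tfidf,
    tokenize,
)


def make_epoch(values, label="heard"):
    data = np.asarray(values, dtype=float)
    return Epoch(
        data=data,
        label=label,
        event=LabeledEvent(kind="left_stimulus", position=0, label=label),
        window_s=data.shape[1] / 1000.0,
    )


class TestTokenize:
    def test_fixed_width_formatting(self):
        doc = tokenize(make_epoch([[0.1, 0.25]]))
        assert doc.tokens == ["0.100", "0.250"]

    def test_unit_value_renders_full_width(self):
        assert tokenize(make_epoch([[1.0, 0.0]])).tokens == ["1.000", "0.000"]

    def test_token_count_is_channels_times_samples(self):
        rng = np.random.default_rng(0)
        epoch = make_epoch(np.round(rng.random((8, 1400)), 3))
        assert len(tokenize(epoch).tokens) == 8 * 1400

    def test_channel_major_order(self):
        doc = tokenize(make_epoch([[0.1, 0.2], [0.3, 0.4]]))
        assert doc.tokens == ["0.100", "0.200", "0.300", "0.400"]

    def test_channel_tagged_variant(self):
        doc = tokenize(make_epoch([[0.1], [0.1]]), channel_tags=True)
        assert doc.tokens == ["c01:0.100", "c02:0.100"]

    @pytest.mark.parametrize("bad", [[[0.1234]], [[-0.001]], [[1.001]]])
    def test_off_grid_values_rejected(self, bad):
        with pytest.raises(GridError):
            tokenize(make_epoch(bad))


class TestVocabulary:
    def test_sorted_unique_union(self):
        corpus = [TokenDocument(["0.100", "0.250"]), TokenDocument(["0.100"])]
        assert build_vocabulary(corpus).terms == ("0.100", "0.250")

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])

    def test_lexicographic_equals_numeric_order(self):
        assert "0.090" < "0.100"
        vocab = build_vocabulary([TokenDocument(["0.100", "0.090", "1.000"])])
        assert vocab.terms == ("0.090", "0.100", "1.000")

    def test_grid_bound(self):
        rng = np.random.default_rng(5)
        epoch = make_epoch(np.round(rng.random((4, 5000)), 3))
        vocab = build_vocabulary([tokenize(epoch)])
        assert len(vocab) <= 1001


# Worked count-vectorizer example: three short texts over an 8-word
# vocabulary, with the expected counts per (document, word).
_WORKED_DOCS = [
    ["this", "study", "text", "example"],
    ["a", "source", "text", "example", "example", "vector"],
    ["a", "this", "study", "source", "text", "text", "time"],
]
_WORKED_EXPECTED = {
    "a": [0, 1, 1],
    "this": [1, 0, 1],
    "study": [1, 0, 1],
    "source": [0, 1, 1],
    "text": [1, 1, 2],
    "example": [1, 2, 0],
    "vector": [0, 1, 0],
    "time": [0, 0, 1],
}


class TestCountVectorize:
    def test_worked_word_example(self):
        corpus = [TokenDocument(list(doc)) for doc in _WORKED_DOCS]
        vocab = build_vocabulary(corpus)
        counts = count_vectorize(corpus, vocab).toarray()
        assert vocab.terms == tuple(sorted(_WORKED_EXPECTED))
        for word, column in _WORKED_EXPECTED.items():
            assert list(counts[:, vocab.index[word]]) == column

    def test_row_sums_equal_document_lengths(self):
        corpus = [TokenDocument(list(doc)) for doc in _WORKED_DOCS]
        counts = count_vectorize(corpus, build_vocabulary(corpus))
        assert list(np.asarray(counts.sum(axis=1)).ravel()) == [4, 6, 7]

    def test_empty_document_gives_zero_row(self):
        vocab = Vocabulary(("0.100",))
        counts = count_vectorize([TokenDocument([])], vocab)
        assert counts.toarray().tolist() == [[0]]

    def test_out_of_vocabulary_ignored_by_default(self):
        vocab = Vocabulary(("0.100",))
        counts = count_vectorize([TokenDocument(["0.100", "0.900"])], vocab)
        assert counts.toarray().tolist() == [[1]]
        with pytest.raises(ValueError, match="0.900"):
            count_vectorize(
                [TokenDocument(["0.100", "0.900"])], vocab, out_of_vocabulary="error"
            )

    @given(st.permutations(list(range(7))))
    def test_token_order_does_not_change_counts(self, order):
        base = ["0.100", "0.100", "0.250", "0.300", "0.300", "0.300", "1.000"]
        vocab = build_vocabulary([TokenDocument(base)])
        reference = count_vectorize([TokenDocument(base)], vocab).toarray()
        shuffled = [base[i] for i in order]
        assert np.array_equal(
            count_vectorize([TokenDocument(shuffled)], vocab).toarray(), reference
        )


class TestIdf:
    def test_ubiquitous_term_has_unit_idf(self):
        assert idf([5], n_docs=5) == pytest.approx([1.0])

    def test_rare_term_value(self):
        assert idf([1], n_docs=3) == pytest.approx([math.log(2) + 1])

    def test_single_document_corpus(self):
        assert idf([1], n_docs=1) == pytest.approx([1.0])

    def test_zero_document_frequency_rejected(self):
        with pytest.raises(ValueError):
            idf([0], n_docs=3)

    def test_idf_at_least_one(self):
        rng = np.random.default_rng(2)
        df = rng.integers(1, 21, size=50)
        assert np.all(idf(df, n_docs=20) >= 1.0)


class TestTfidf:
    def test_single_term_single_doc(self):
        weights = tfidf(np.array([[1]]), idf([1], 1))
        assert np.allclose(weights.toarray(), [[1.0]])

    def test_zero_count_gives_zero_weight(self):
        counts = np.array([[2, 0], [1, 1]])
        weights = tfidf(counts, idf(document_frequency(counts), 2), l2_normalize=False)
        assert weights.toarray()[0, 1] == 0.0

    def test_zero_row_survives_normalization(self):
        counts = np.array([[0, 0], [1, 1]])
        weights = tfidf(counts, np.array([1.0, 1.0]))
        assert np.all(weights.toarray()[0] == 0.0)
        assert np.linalg.norm(weights.toarray()[1]) == pytest.approx(1.0)

    def test_rows_unit_norm_when_normalized(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 4, size=(6, 9))
        counts[0] += 1  # no all-zero doc
        fm_counts = counts
        df = document_frequency(fm_counts)
        df = np.maximum(df, 1)
        weights = tfidf(fm_counts, idf(df, 6)).toarray()
        norms = np.linalg.norm(weights, axis=1)
        assert norms[norms > 0] == pytest.approx(np.ones((norms > 0).sum()))


def naive_tfidf(docs: list[list[str]], l2_normalize: bool) -> tuple[list[str], np.ndarray]:
    """Brute-force dictionary reimplementation: loop terms x documents."""
    terms = sorted({t for doc in docs for t in doc})
    n = len(docs)
    weights = np.zeros((n, len(terms)))
    for j, term in enumerate(terms):
        df = sum(1 for doc in docs if term in doc)
        term_idf = math.log((n + 1) / (df + 1)) + 1
        for i, doc in enumerate(docs):
            weights[i, j] = doc.count(term) * term_idf
    if l2_normalize:
        for i in range(n):
            norm = math.sqrt(sum(w * w for w in weights[i]))
            if norm > 0:
                weights[i] /= norm
    return terms, weights


@pytest.mark.parametrize("l2_normalize", [True, False])
def test_pipeline_matches_bruteforce_oracle(l2_normalize):
    """Vectorizer + idf + weighting vs the naive loop, element-wise."""
    rng = np.random.default_rng(7)
    alphabet = [f"{v / 1000:.3f}" for v in range(0, 1000, 50)]
    for _ in range(50):
        docs = [
            list(rng.choice(alphabet, size=rng.integers(1, 15)))
            for _ in range(rng.integers(2, 11))
        ]
        corpus = [TokenDocument(list(d)) for d in docs]
        fm = fit_feature_matrix(corpus=corpus, l2_normalize=l2_normalize)
        terms, expected = naive_tfidf(docs, l2_normalize)
        assert list(fm.vocabulary.terms) == terms
        assert np.allclose(fm.weights.toarray(), expected, atol=1e-12)


def test_pipeline_matches_sklearn_vectorizer():
    """Cross-check against sklearn's TfidfVectorizer on the same corpus."""
    from sklearn.feature_extraction.text import TfidfVectorizer

    rng = np.random.default_rng(11)
    alphabet = [f"{v / 1000:.3f}" for v in range(0, 500, 25)]
    docs = [list(rng.choice(alphabet, size=20)) for _ in range(8)]
    fm = fit_feature_matrix(corpus=[TokenDocument(list(d)) for d in docs])
    vec = TfidfVectorizer(analyzer=lambda d: d, norm="l2", smooth_idf=True)
    expected = vec.fit_transform(docs)
    order = np.argsort(vec.get_feature_names_out())
    assert list(np.array(vec.get_feature_names_out())[order]) == list(fm.vocabulary.terms)
    assert np.allclose(fm.weights.toarray(), expected.toarray()[:, order], atol=1e-12)


def test_fast_numeric_path_equals_string_path():
    rng = np.random.default_rng(13)
    epochs = [make_epoch(np.round(rng.random((3, 40)), 3)) for _ in range(6)]
    counts_fast, vocab_fast = counts_from_epochs(epochs)
    corpus = [tokenize(e) for e in epochs]
    vocab_str = build_vocabulary(corpus)
    counts_str = count_vectorize(corpus, vocab_str)
    assert vocab_fast.terms == vocab_str.terms
    assert np.array_equal(counts_fast.toarray(), counts_str.toarray())


def test_feature_matrix_invariants():
    rng = np.random.default_rng(17)
    epochs = [make_epoch(np.round(rng.random((2, 30)), 3)) for _ in range(5)]
    fm = fit_feature_matrix(epochs=epochs)
    assert fm.n_docs == 5
    assert np.all(fm.doc_freq >= 1)
    # weights vanish exactly where counts vanish
    assert np.array_equal(fm.weights.toarray() == 0, fm.counts.toarray() == 0)
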