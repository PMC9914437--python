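"""Signal-to-text encoding: rounded samples as words, TF-IDF as weights.

Each epoch becomes a *document*: its rounded sample values, read channel 1
first and in time order within a channel, rendered as fixed-width strings
("0.000" .. "1.000").  A Count Vectorizer over the sorted vocabulary then
gives per-document term counts — effectively a value histogram — and
TF-IDF reweights terms by how document-specific they are:

    tfidf(t, d) = tf(t, d) * idf(t),   idf(t) = ln((n + 1) / (df(t) + 1)) + 1

with ``n`` documents, ``df(t)`` the number of documents containing term
``t``, and raw counts as tf.  The "+1" smoothing keeps idf finite and
>= 1; rows are L2-normalized by default (a flag exposes the raw product).

Because tokens are fixed-width decimals on a bounded grid, lexicographic
vocabulary order equals numeric order and the vocabulary can never exceed
1001 terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .epochs import Epoch

__all__ = [
    "GRID_SIZE",
    "TokenDocument",
    "Vocabulary",
    "FeatureMatrix",
    "GridError",
    "tokenize",
    "epoch_token_ids",
    "build_vocabulary",
    "count_vectorize",
    "counts_from_epochs",
    "idf",
    "tfidf",
    "fit_feature_matrix",
    "save_feature_matrix",
]

#: Number of distinct tokens on the 3-decimal [0, 1] grid.
GRID_SIZE: int = 1001

#: All grid tokens in (equivalently lexicographic and numeric) order.
_GRID_TOKENS: np.ndarray = np.array([f"{i / 1000:.3f}" for i in range(GRID_SIZE)])


class GridError(ValueError):
    """An epoch value is not on the rounded [0, 1] grid."""


@dataclass
class TokenDocument:
    """One epoch rendered as an ordered token sequence."""

    tokens: list[str]
    source: object = None


@dataclass(frozen=True)
class Vocabulary:
    """Sorted, duplicate-free term list with term -> column lookup."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.terms) != sorted(set(self.terms)):
            raise ValueError("vocabulary terms must be sorted and unique")

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class FeatureMatrix:
    """Counts and TF-IDF weights over a shared vocabulary."""

    counts: sp.csr_matrix
    weights: sp.csr_matrix
    vocabulary: Vocabulary
    doc_freq: np.ndarray
    n_docs: int


def epoch_token_ids(epoch: Epoch) -> np.ndarray:
    """Grid index (0..1000) per sample, channel-major order.

    Raises :class:`GridError` when a value is off the rounded [0, 1] grid;
    epochs must come from the preprocessing chain (normalize + round).
    """
    values = np.asarray(epoch.data, dtype=float).ravel()  # row-major: channel 1 first
    scaled = values * 1000.0
    ids = np.rint(scaled).astype(np.int64)
    if (
        np.any(values < 0)
        or np.any(values > 1)
        or np.any(np.abs(scaled - ids) > 1e-6)
    ):
        raise GridError("epoch values must lie on the 3-decimal [0, 1] grid")
    return ids


def tokenize(epoch: Epoch, channel_tags: bool = False) -> TokenDocument:
    """Render an epoch as fixed-width "d.ddd" tokens.

    With ``channel_tags`` each token is prefixed "c<nn>:" so identical
    values on different channels become distinct words (ablation variant;
    the default treats values alone as the words).
    """
    ids = epoch_token_ids(epoch)
    tokens = _GRID_TOKENS[ids]
    if channel_tags:
        n_ch, n_t = epoch.data.shape
        chans = np.repeat([f"c{c + 1:02d}:" for c in range(n_ch)], n_t)
        tokens = np.char.add(chans, tokens)
    return TokenDocument(tokens=tokens.tolist(), source=epoch.event)


def build_vocabulary(corpus: Sequence[TokenDocument]) -> Vocabulary:
    """Sorted unique terms over the corpus."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    terms = sorted(set().union(*(doc.tokens for doc in corpus)))
    return Vocabulary(terms=tuple(terms))


def count_vectorize(
    corpus: Sequence[TokenDocument],
    vocabulary: Vocabulary,
    out_of_vocabulary: str = "ignore",
) -> sp.csr_matrix:
    """documents x terms count matrix.

    Tokens outside the vocabulary are silently dropped by default (the
    vocabulary is frozen on training data); ``out_of_vocabulary="error"``
    raises instead.
    """
    if out_of_vocabulary not in ("ignore", "error"):
        raise ValueError("out_of_vocabulary must be 'ignore' or 'error'")
    index = vocabulary.index
    matrix = sp.lil_matrix((len(corpus), len(vocabulary)), dtype=np.int64)
    for d, doc in enumerate(corpus):
        for token in doc.tokens:
            col = index.get(token)
            if col is None:
                if out_of_vocabulary == "error":
                    raise ValueError(f"token {token!r} not in vocabulary")
                continue
            matrix[d, col] += 1
    return matrix.tocsr()


def counts_from_epochs(
    epochs: Sequence[Epoch], vocabulary: Vocabulary | None = None
) -> tuple[sp.csr_matrix, Vocabulary]:
    """Fast numeric path: token counts per epoch without building strings.

    Equivalent to ``count_vectorize(map(tokenize, epochs), vocabulary)``
    with the vocabulary built from these epochs when not supplied; the
    value histogram per epoch is computed directly on the grid indices.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    grid_counts = np.stack(
        [np.bincount(epoch_token_ids(e), minlength=GRID_SIZE) for e in epochs]
    )
    if vocabulary is None:
        present = np.flatnonzero(grid_counts.sum(axis=0) > 0)
        vocabulary = Vocabulary(terms=tuple(_GRID_TOKENS[present]))
        counts = grid_counts[:, present]
    else:
        cols = np.array(
            [int(round(float(t) * 1000)) for t in vocabulary.terms], dtype=np.int64
        )
        counts = grid_counts[:, cols]
    return sp.csr_matrix(counts), vocabulary


def idf(doc_freq: np.ndarray | Sequence[int], n_docs: int) -> np.ndarray:
    """Smoothed inverse document frequency: ln((n+1)/(df+1)) + 1.

    Natural log; df = n gives idf = 1, so idf >= 1 for any term that
    actually occurs.
    """
    df = np.asarray(doc_freq, dtype=float)
    if n_docs < 1:
        raise ValueError("need at least one document")
    if np.any(df < 1) or np.any(df > n_docs):
        raise ValueError("document frequency must satisfy 1 <= df <= n_docs")
    return np.log((n_docs + 1.0) / (df + 1.0)) + 1.0


def tfidf(
    counts: sp.spmatrix | np.ndarray,
    idf_weights: np.ndarray,
    l2_normalize: bool = True,
) -> sp.csr_matrix:
    """Per-document TF-IDF: raw count x idf, optionally L2-normalized rows.

    An all-zero document row stays zero under normalization.
    """
    counts = sp.csr_matrix(counts, dtype=float)
    if counts.shape[1] != len(idf_weights):
        raise ValueError("idf length must match the number of terms")
    weights = counts.multiply(np.asarray(idf_weights, dtype=float)[None, :]).tocsr()
    if l2_normalize:
        norms = np.sqrt(np.asarray(weights.multiply(weights).sum(axis=1)).ravel())
        norms[norms == 0] = 1.0
        weights = sp.diags(1.0 / norms) @ weights
    return sp.csr_matrix(weights)


def document_frequency(counts: sp.spmatrix | np.ndarray) -> np.ndarray:
    counts = sp.csr_matrix(counts)
    return np.asarray((counts > 0).sum(axis=0)).ravel()


def fit_feature_matrix(
    corpus: Sequence[TokenDocument] | None = None,
    epochs: Sequence[Epoch] | None = None,
    l2_normalize: bool = True,
) -> FeatureMatrix:
    """Vocabulary + counts + TF-IDF in one step, from docs or epochs."""
    if (corpus is None) == (epochs is None):
        raise ValueError("pass exactly one of corpus= or epochs=")
    if epochs is not None:
        counts, vocabulary = counts_from_epochs(epochs)
    else:
        assert corpus is not None
        vocabulary = build_vocabulary(corpus)
        counts = count_vectorize(corpus, vocabulary)
    df = document_frequency(counts)
    n_docs = counts.shape[0]
    weights = tfidf(counts, idf(df, n_docs), l2_normalize=l2_normalize)
    return FeatureMatrix(
        counts=counts, weights=weights, vocabulary=vocabulary, doc_freq=df, n_docs=n_docs
    )


def save_feature_matrix(fm: FeatureMatrix, basepath: str | Path) -> None:
    """MTX pair (counts + weights) plus a one-term-per-line vocabulary file."""
    import scipy.io as sio

    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(basepath) + ".counts.mtx", fm.counts)
    sio.mmwrite(str(basepath) + ".tfidf.mtx", fm.weights)
    Path(str(basepath) + ".vocab.txt").write_text("\n".join(fm.vocabulary.terms) + "\n")
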