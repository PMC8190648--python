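"""Linear SVM baseline over TF-IDF n-gram features.

The comparison model: token n-grams (bigrams, optionally with
unigrams) are extracted from the training text, filtered by a minimum
raw-corpus-frequency threshold, TF-IDF weighted, and fed to a linear
multiclass SVM. Per-label probabilities come from a softmax over the
one-vs-rest decision margins — cross-validated Platt scaling is not
viable here because long-tailed label laws guarantee singleton classes.

The frequency thresholds mirror the study conditions: terms must
appear at least 4 times in procedure-text-only inputs and at least 15
times when the preoperative diagnosis is appended.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer
from sklearn.svm import LinearSVC

__all__ = ["FeatureSpec", "Featurizer", "SvmBaseline", "MIN_COUNT_PROCEDURE",
           "MIN_COUNT_COMBINED"]

#: Raw-frequency thresholds for the two input modes.
MIN_COUNT_PROCEDURE = 4
MIN_COUNT_COMBINED = 15


def _whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


@dataclass(frozen=True)
class FeatureSpec:
    """Fitted vocabulary and IDF weights of the featurizer."""

    vocabulary: tuple[str, ...]
    idf: np.ndarray
    min_count: int
    include_unigrams: bool


class Featurizer:
    """TF-IDF n-gram features with a raw-corpus-frequency cutoff.

    ``min_count`` applies to total occurrences across the training
    corpus (not document frequency), before TF-IDF weighting. Unseen
    text is transformed with the training vocabulary only; text sharing
    no n-gram with it becomes an all-zero row. Unigrams are included by
    default because one-token texts produce no bigram at all.
    """

    def __init__(self, min_count: int = MIN_COUNT_PROCEDURE,
                 include_unigrams: bool = True):
        if min_count < 1:
            raise ValueError("min_count must be positive")
        self.min_count = min_count
        self.include_unigrams = include_unigrams
        self.spec: FeatureSpec | None = None
        self._counter: CountVectorizer | None = None
        self._tfidf: TfidfTransformer | None = None

    def fit_transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        if not texts:
            raise ValueError("empty training corpus")
        ngram_range = (1, 2) if self.include_unigrams else (2, 2)
        counter = CountVectorizer(
            tokenizer=_whitespace_tokenizer, ngram_range=ngram_range,
            lowercase=False, token_pattern=None)
        counts = counter.fit_transform(texts)
        totals = np.asarray(counts.sum(axis=0)).ravel()
        keep = totals >= self.min_count
        if not keep.any():
            raise ValueError(
                f"no n-gram reaches min_count={self.min_count} in training text")
        vocab = np.array(counter.get_feature_names_out())[keep]
        self._counter = CountVectorizer(
            tokenizer=_whitespace_tokenizer, ngram_range=ngram_range,
            lowercase=False, token_pattern=None,
            vocabulary={v: i for i, v in enumerate(vocab)})
        kept_counts = self._counter.transform(texts)
        self._tfidf = TfidfTransformer()
        X = self._tfidf.fit_transform(kept_counts)
        self.spec = FeatureSpec(
            vocabulary=tuple(vocab), idf=self._tfidf.idf_.copy(),
            min_count=self.min_count, include_unigrams=self.include_unigrams)
        return X

    def transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        if self.spec is None:
            raise RuntimeError("featurizer is not fitted")
        return self._tfidf.transform(self._counter.transform(texts))


class SvmBaseline:
    """Multiclass linear SVM with probability-like outputs.

    The regularization strength C is selected on a validation set from
    a small grid (grid-search in the study's sense, desk-scale here).
    Decision margins are mapped to a per-sample probability simplex by
    softmax; ties in predicted probability break toward the smaller
    code string. Deterministic given ``seed``.
    """

    C_GRID = (0.1, 1.0, 10.0)

    def __init__(self, min_count: int = MIN_COUNT_PROCEDURE,
                 include_unigrams: bool = True, seed: int = 0):
        self.featurizer = Featurizer(min_count, include_unigrams)
        self.seed = seed
        self.classes_: np.ndarray | None = None
        self._clf: LinearSVC | None = None
        self.best_C: float | None = None

    def fit(self, texts: Sequence[str], labels: Sequence[str],
            val_texts: Sequence[str] | None = None,
            val_labels: Sequence[str] | None = None) -> "SvmBaseline":
        labels = np.asarray(labels, dtype=object)
        if len(set(labels)) < 2:
            raise ValueError("training set must contain at least 2 labels")
        X = self.featurizer.fit_transform(list(texts))
        if val_texts is not None and val_labels is not None and len(val_texts):
            Xv = self.featurizer.transform(list(val_texts))
            yv = np.asarray(val_labels, dtype=object)
            best_acc, best_C = -1.0, self.C_GRID[0]
            for C in self.C_GRID:
                clf = LinearSVC(C=C, random_state=self.seed)
                clf.fit(X, labels)
                acc = float((clf.predict(Xv) == yv).mean())
                if acc > best_acc:
                    best_acc, best_C = acc, C
            self.best_C = best_C
        else:
            self.best_C = 1.0
        self._clf = LinearSVC(C=self.best_C, random_state=self.seed)
        self._clf.fit(X, labels)
        self.classes_ = self._clf.classes_.astype(object)
        return self

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        """Per-label probabilities (softmax over decision margins);
        rows are non-negative and sum to one."""
        if self._clf is None:
            raise RuntimeError("model is not fitted")
        X = self.featurizer.transform(list(texts))
        margins = self._clf.decision_function(X)
        if margins.ndim == 1:  # binary: expand to two columns
            margins = np.column_stack([-margins, margins])
        margins = margins - margins.max(axis=1, keepdims=True)
        e = np.exp(margins)
        return e / e.sum(axis=1, keepdims=True)

    def predict_topk(self, texts: Sequence[str], k: int = 3
                     ) -> list[list[tuple[str, float]]]:
        """Top-k (code, probability) per sample, probability descending,
        ties toward the smaller code."""
        proba = self.predict_proba(texts)
        out = []
        for row in proba:
            order = sorted(range(len(row)),
                           key=lambda j: (-row[j], self.classes_[j]))
            kk = min(k, len(row))
            out.append([(str(self.classes_[j]), float(row[j]))
                        for j in order[:kk]])
        return out
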