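"""Step 2 of the coding system: match translations to catalog codes.

Each candidate translation is compared against the canonical
description of every catalog code by string distance, and distances x
are mapped to similarity scores 1/(x + 1), so scores live in (0, 1]
with 1 exactly at distance 0. Scores for a sample's candidates are
merged label-wise by maximum into an M x N score matrix (M samples, N
labels), and the predicted code for sample i is

    prediction_i = argmax_j 1 / (x_ij + 1)

with ties broken toward the lexicographically smallest code.

Two distance metrics capture complementary granularity: Levenshtein
edit distance at the character level of the space-joined sentence, and
Jaccard distance over whitespace-token sets. ``mean`` averages the two
inverse-distance scores (not the raw distances).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .catalog import CodeCatalog
from .corpus import normalize_target
from .nmt import TranslationCandidates

__all__ = [
    "METRICS",
    "levenshtein",
    "jaccard_distance",
    "inverse_distance",
    "ScoreMatrix",
    "Prediction",
    "score_matrix",
    "predict",
]

METRICS = ("levenshtein", "jaccard", "mean")


def levenshtein(a: str, b: str) -> int:
    """Character-level edit distance (insertions, deletions,
    substitutions); symmetric and satisfies the triangle inequality."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def jaccard_distance(a: str, b: str) -> float:
    """1 - |A ∩ B| / |A ∪ B| over whitespace-token sets.

    Two empty token sets are identical, hence distance 0.
    """
    ta, tb = set(a.split()), set(b.split())
    union = ta | tb
    if not union:
        return 0.0
    return 1.0 - len(ta & tb) / len(union)


def inverse_distance(x: float) -> float:
    """Similarity score 1/(x+1): maps [0, inf) onto (0, 1], strictly
    decreasing, with score 1 iff distance 0."""
    if x < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / (x + 1.0)


@dataclass
class ScoreMatrix:
    """Per-sample, per-label inverse-distance similarity scores.

    ``scores`` is M x N with every entry in (0, 1]; ``per_candidate``
    optionally retains the raw M x k x N scores before the label-wise
    max merge (k padded with 0 where samples had fewer candidates).
    """

    scores: np.ndarray
    label_order: list[str]
    per_candidate: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_labels(self) -> int:
        return self.scores.shape[1]

    def __post_init__(self) -> None:
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-dimensional")
        if self.scores.shape[1] != len(self.label_order):
            raise ValueError("label_order length must match score columns")
        if self.scores.size and (self.scores.min() <= 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in (0, 1]")


@dataclass(frozen=True)
class Prediction:
    """Predicted codes for one sample: best first, then the top-3 list."""

    index: int
    top1: str
    top3: tuple[str, ...]
    top1_score: float

    def __post_init__(self) -> None:
        if not self.top3 or self.top3[0] != self.top1:
            raise ValueError("top1 must be the first element of top3")
        if len(set(self.top3)) != len(self.top3):
            raise ValueError("top3 codes must be distinct")


def _metric_scores(sentence: str, terms: Sequence[str], metric: str) -> np.ndarray:
    if metric == "levenshtein":
        return np.array([inverse_distance(levenshtein(sentence, t)) for t in terms])
    if metric == "jaccard":
        return np.array([inverse_distance(jaccard_distance(sentence, t)) for t in terms])
    if metric == "mean":
        lev = _metric_scores(sentence, terms, "levenshtein")
        jac = _metric_scores(sentence, terms, "jaccard")
        return (lev + jac) / 2.0
    raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")


def score_matrix(
    samples: Sequence[TranslationCandidates],
    catalog: CodeCatalog,
    metric: str = "mean",
    keep_per_candidate: bool = True,
) -> ScoreMatrix:
    """Score every sample's candidates against every catalog label.

    Catalog descriptions are normalized into the same text space as
    the translations (lowercase, punctuation stripped). The merged
    score for (sample, label) is the maximum over that sample's
    candidates.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    terms = [normalize_target(t) for t in catalog.terms]
    max_k = 0
    for i, s in enumerate(samples):
        if not s.candidates:
            raise ValueError(f"sample {i} has no candidates")
        max_k = max(max_k, len(s.candidates))
    per_cand = np.zeros((len(samples), max_k, len(terms)))
    for i, s in enumerate(samples):
        for c, (sentence, _) in enumerate(s.candidates):
            per_cand[i, c] = _metric_scores(sentence, terms, metric)
    merged = per_cand.max(axis=1)
    return ScoreMatrix(
        scores=merged,
        label_order=list(catalog.codes),
        per_candidate=per_cand if keep_per_candidate else None,
    )


def _argmax_smallest_code(scores: np.ndarray, labels: Sequence[str]) -> int:
    """Index of the max score; ties go to the smallest code string."""
    best = scores.max()
    tied = np.nonzero(scores == best)[0]
    return min(tied, key=lambda j: labels[j])


def predict(matrix: ScoreMatrix) -> list[Prediction]:
    """Argmax prediction per sample from the merged score matrix.

    top1 is the merged-score argmax. top3 takes each candidate's
    best-matching label in beam order (requires ``per_candidate``),
    deduplicates preserving order, and pads from the merged-score
    ranking when fewer than three distinct labels emerge. top1 always
    heads top3.
    """
    labels = matrix.label_order
    out: list[Prediction] = []
    for i in range(matrix.n_samples):
        merged = matrix.scores[i]
        j1 = _argmax_smallest_code(merged, labels)
        top3: list[str] = [labels[j1]]
        if matrix.per_candidate is not None:
            for c in range(matrix.per_candidate.shape[1]):
                row = matrix.per_candidate[i, c]
                if row.max() <= 0:  # padding row for a missing candidate
                    continue
                code = labels[_argmax_smallest_code(row, labels)]
                if code not in top3:
                    top3.append(code)
                if len(top3) == 3:
                    break
        if len(top3) < 3:
            # pad from the merged ranking (score desc, code asc on ties)
            order = sorted(range(len(labels)),
                           key=lambda j: (-merged[j], labels[j]))
            for j in order:
                if labels[j] not in top3:
                    top3.append(labels[j])
                if len(top3) == 3 or len(top3) == len(labels):
                    break
        out.append(Prediction(index=i, top1=labels[j1],
                              top3=tuple(top3[:3]),
                              top1_score=float(merged[j1])))
    return out
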