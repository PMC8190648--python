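from functools import lru_cache
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codetrans.catalog import CodeCatalog, CodeEntry
from codetrans.nmt import TranslationCandidates
from codetrans.transform import (METRICS, Prediction, ScoreMatrix,
                                 inverse_distance, jaccard_distance,
                                 levenshtein, predict, score_matrix)


def reference_levenshtein(a: str, b: str) -> int:
    """Exhaustive recursive oracle, independent of the implementation."""
    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1,
                   rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
    return rec(len(a), len(b))


class TestLevenshtein:
    def test_classic_example(self):
        assert levenshtein("kitten", "sitting") == 3

    @pytest.mark.parametrize("s", ["", "a", "procedure on knee"])
    def test_identity(self, s):
        assert levenshtein(s, s) == 0

    def test_empty_vs_nonempty(self):
        assert levenshtein("", "abc") == 3
        assert levenshtein("abc", "") == 3

    @given(st.text(alphabet="ab", max_size=8), st.text(alphabet="ab", max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_recursive_oracle(self, a, b):
        assert levenshtein(a, b) == reference_levenshtein(a, b)

    @given(st.text(alphabet="abc", max_size=6), st.text(alphabet="abc", max_size=6),
           st.text(alphabet="abc", max_size=6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_metric_axioms(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestJaccard:
    def test_identical_token_sets(self):
        assert jaccard_distance("knee repair", "repair knee repair") == 0.0

    def test_disjoint_token_sets(self):
        assert jaccard_distance("a b", "c d") == 1.0

    def test_partial_overlap(self):
        assert jaccard_distance("a b", "b c") == pytest.approx(2 / 3)

    def test_both_empty(self):
        assert jaccard_distance("", "") == 0.0

    @given(st.lists(st.sampled_from("abcdef"), max_size=6),
           st.lists(st.sampled_from("abcdef"), max_size=6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_set_arithmetic(self, ta, tb):
        a, b = " ".join(ta), " ".join(tb)
        sa, sb = set(ta), set(tb)
        expected = 1 - len(sa & sb) / len(sa | sb) if (sa | sb) else 0.0
        assert jaccard_distance(a, b) == pytest.approx(expected)


class TestInverseDistance:
    @given(st.one_of(st.just(0.0),
                     st.floats(min_value=1e-9, max_value=1e6)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_range_and_identity(self, x):
        s = inverse_distance(x)
        assert 0 < s <= 1
        assert (s == 1.0) == (x == 0.0)

    def test_strictly_decreasing(self):
        xs = [0.0, 0.5, 1.0, 2.0, 10.0]
        scores = [inverse_distance(x) for x in xs]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_unit_distance_halves_score(self):
        assert inverse_distance(1) == 0.5

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            inverse_distance(-0.1)


def _catalog(terms):
    return CodeCatalog(entries=[CodeEntry(f"{100 + 4 * i:05d}", t)
                                for i, t in enumerate(terms)])


def _sample(*sentences):
    scores = [0.0 - 0.1 * i for i in range(len(sentences))]
    return TranslationCandidates(
        source=sentences[0], candidates=tuple(zip(sentences, scores)),
        k=len(sentences))


class TestScoreMatrix:
    def test_exact_candidate_scores_one(self):
        cat = _catalog(["left knee repair", "open heart bypass"])
        m = score_matrix([_sample("left knee repair")], cat, "levenshtein")
        assert m.scores[0, 0] == 1.0
        assert m.scores[0, 1] < 1.0

    def test_candidates_merge_by_max(self):
        cat = _catalog(["aaa", "bbb"])
        m = score_matrix([_sample("aaa", "bbb")], cat, "levenshtein")
        # each candidate matches one term exactly; max-merge keeps both at 1
        assert m.scores[0].tolist() == [1.0, 1.0]

    def test_mean_metric_averages_inverse_scores(self):
        cat = _catalog(["a b"])
        m = score_matrix([_sample("a c")], cat, "mean")
        lev = inverse_distance(levenshtein("a c", "a b"))
        jac = inverse_distance(jaccard_distance("a c", "a b"))
        assert m.scores[0, 0] == pytest.approx((lev + jac) / 2)

    def test_dimensions_and_bounds(self):
        cat = _catalog(["alpha beta", "gamma delta", "epsilon zeta"])
        samples = [_sample("alpha", "beta"), _sample("gamma")]
        m = score_matrix(samples, cat, "mean")
        assert (m.n_samples, m.n_labels) == (2, 3)
        assert m.per_candidate.shape == (2, 2, 3)
        assert 0 < m.scores.min() and m.scores.max() <= 1

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            score_matrix([_sample("x")], CodeCatalog(entries=[]), "mean")

    def test_bad_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            score_matrix([_sample("x")], _catalog(["y"]), "hamming")


class TestPredict:
    def test_single_label_catalog(self):
        cat = _catalog(["only term"])
        preds = predict(score_matrix([_sample("whatever"), _sample("x")], cat))
        assert all(p.top1 == "00100" for p in preds)

    def test_exact_match_wins(self):
        cat = _catalog(["left knee repair", "open heart bypass", "ear exam"])
        preds = predict(score_matrix([_sample("open heart bypass")], cat,
                                     "levenshtein"))
        assert preds[0].top1 == "00104"
        assert preds[0].top1_score == 1.0

    def test_tie_breaks_to_smaller_code(self):
        m = ScoreMatrix(scores=np.array([[0.5, 0.5]]),
                        label_order=["00108", "00104"])
        assert predict(m)[0].top1 == "00104"

    def test_top3_headed_by_top1_and_distinct(self):
        cat = _catalog(["alpha beta", "gamma delta", "epsilon zeta", "eta theta"])
        samples = [_sample("alpha beta", "gamma delta", "gamma delta")]
        preds = predict(score_matrix(samples, cat))
        p = preds[0]
        assert p.top3[0] == p.top1
        assert len(set(p.top3)) == len(p.top3) == 3

    def test_permutation_invariance(self):
        terms = ["left knee repair", "open heart bypass", "ear exam canal"]
        samples = [_sample("opn heart bypass"), _sample("ear exam")]
        base = predict(score_matrix(samples, _catalog(terms), "mean"))
        # permute catalog order: predicted codes must not change
        perm_entries = [CodeEntry("00108", "open heart bypass"),
                        CodeEntry("00100", "ear exam canal"),
                        CodeEntry("00104", "left knee repair")]
        perm = CodeCatalog(entries=perm_entries)
        permuted = predict(score_matrix(samples, perm, "mean"))
        # map codes to terms for comparison
        base_terms = [_catalog(terms).lookup(p.top1) for p in base]
        perm_terms = [perm.lookup(p.top1) for p in permuted]
        assert base_terms == perm_terms

    def test_prediction_invariants_enforced(self):
        with pytest.raises(ValueError):
            Prediction(index=0, top1="a", top3=("b", "a"), top1_score=1.0)
        with pytest.raises(ValueError):
            Prediction(index=0, top1="a", top3=("a", "b", "b"), top1_score=1.0)

    @pytest.mark.parametrize("metric", METRICS)
    def test_top3_contains_top1(self, metric):
        cat = _catalog(["alpha beta", "gamma delta", "epsilon zeta"])
        samples = [_sample("alpha bta", "gamma delta"), _sample("epsilon")]
        for p in predict(score_matrix(samples, cat, metric)):
            assert p.top1 in p.top3
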