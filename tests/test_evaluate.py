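import math

import numpy as np
import pytest

from codetrans.evaluate import (BOOTSTRAP_REPS, BOOTSTRAP_SAMPLE_SIZE,
                                EvalReport, bootstrap_ci, corpus_bleu,
                                evaluate_predictions, group_by_sample_size,
                                per_group_report, topk_accuracy)


class TestTopkAccuracy:
    def test_all_correct(self):
        preds = [["a", "b", "c"]] * 4
        assert topk_accuracy(preds, ["a"] * 4, 1) == 1.0

    def test_truth_in_second_position(self):
        preds = [["a", "b", "c"]] * 4
        assert topk_accuracy(preds, ["b"] * 4, 1) == 0.0
        assert topk_accuracy(preds, ["b"] * 4, 3) == 1.0

    def test_top3_bounds_top1(self):
        rng = np.random.default_rng(0)
        preds = [[str(i) for i in rng.choice(9, 3, replace=False)]
                 for _ in range(50)]
        truth = [str(rng.integers(9)) for _ in range(50)]
        assert topk_accuracy(preds, truth, 3) >= topk_accuracy(preds, truth, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            topk_accuracy([["a"]], ["a", "b"], 1)


class TestBootstrap:
    def test_degenerate_all_correct(self):
        point, lo, hi = bootstrap_ci([["a"]] * 30, ["a"] * 30, 1, reps=100, seed=0)
        assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_interval_brackets_point(self):
        rng = np.random.default_rng(1)
        preds = [["a"] if rng.random() < 0.8 else ["b"] for _ in range(400)]
        truth = ["a"] * 400
        for seed in range(5):
            point, lo, hi = bootstrap_ci(preds, truth, 1, reps=200, seed=seed)
            assert lo <= point <= hi

    def test_default_study_conditions(self):
        assert BOOTSTRAP_REPS == 500 and BOOTSTRAP_SAMPLE_SIZE == 20_000

    def test_deterministic_given_seed(self):
        preds = [["a"], ["b"], ["a"], ["a"]] * 25
        truth = ["a"] * 100
        assert bootstrap_ci(preds, truth, 1, seed=9) == \
            bootstrap_ci(preds, truth, 1, seed=9)

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(2)
        hits = rng.random(50_000) < 0.8
        preds = [["a"] if h else ["b"] for h in hits]
        truth = ["a"] * len(hits)
        _, lo_s, hi_s = bootstrap_ci(preds, truth, 1, reps=300,
                                     sample_size=2_000, seed=4)
        _, lo_l, hi_l = bootstrap_ci(preds, truth, 1, reps=300,
                                     sample_size=20_000, seed=4)
        assert (hi_l - lo_l) < (hi_s - lo_s)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([], [], 1)


class TestCorpusBleu:
    def test_perfect_match(self):
        refs = ["anesthesia for procedures on knee joint"] * 3
        assert corpus_bleu(refs, refs) == pytest.approx(1.0)

    def test_disjoint_corpora_near_zero(self):
        assert corpus_bleu(["x y z w v"] * 3, ["a b c d e"] * 3) < 0.01

    def test_single_pair_hand_computed(self):
        # p1=4/5, p2=3/4, p3=2/3, p4=1/2, brevity penalty 1
        # BLEU = (4/5 * 3/4 * 2/3 * 1/2)^(1/4) = 0.2^0.25
        val = corpus_bleu(["a b c d e"], ["a b c d f"])
        assert val == pytest.approx(0.2 ** 0.25)

    def test_brevity_penalty_hand_computed(self):
        # hypothesis shorter than reference: all precisions 1, bp=exp(1-6/4)
        val = corpus_bleu(["a b c d"], ["a b c d e f"])
        assert val == pytest.approx(math.exp(1 - 6 / 4))

    def test_order_invariance(self):
        hyps = ["a b c", "d e f g", "h i"]
        refs = ["a b d", "d e f f", "h j"]
        perm = [2, 0, 1]
        assert corpus_bleu(hyps, refs) == pytest.approx(
            corpus_bleu([hyps[i] for i in perm], [refs[i] for i in perm]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            corpus_bleu(["a"], ["a", "b"])


class TestGrouping:
    def test_ten_groups_near_equal_cardinality(self):
        counts = {f"{i:05d}": i % 40 for i in range(272)}
        spec = group_by_sample_size(counts, 10)
        sizes = [list(spec.assignment.values()).count(g) for g in range(10)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 272

    def test_group_index_increases_with_count(self):
        counts = {"a": 1, "b": 5, "c": 100, "d": 2, "e": 50, "f": 10}
        spec = group_by_sample_size(counts, 3)
        assert spec.assignment["a"] < spec.assignment["f"] < spec.assignment["c"]
        assert all(lo <= hi for lo, hi in spec.boundaries)

    def test_single_group_contains_every_code(self):
        counts = {"a": 3, "b": 9}
        spec = group_by_sample_size(counts, 1)
        assert set(spec.assignment) == {"a", "b"}
        assert spec.boundaries == ((3, 9),)

    def test_partition_property(self):
        counts = {f"{i:05d}": (i * 7) % 13 for i in range(100)}
        spec = group_by_sample_size(counts, 10)
        assert set(spec.assignment) == set(counts)

    def test_equal_counts_still_balanced(self):
        counts = {f"{i:05d}": 5 for i in range(25)}
        spec = group_by_sample_size(counts, 5)
        sizes = [list(spec.assignment.values()).count(g) for g in range(5)]
        assert sizes == [5] * 5


class TestPerGroupReport:
    def test_single_populated_group_matches_overall(self):
        counts = {"a": 1, "b": 50}
        spec = group_by_sample_size(counts, 2)
        preds = [["b"], ["b"], ["a"]]
        truth = ["b", "b", "b"]
        rep = per_group_report(preds, truth, spec, 1)
        assert rep == {spec.assignment["b"]: pytest.approx(2 / 3)}

    def test_empty_groups_absent_not_zero(self):
        counts = {"a": 1, "b": 50}
        spec = group_by_sample_size(counts, 2)
        rep = per_group_report([["b"]], ["b"], spec, 1)
        assert spec.assignment["a"] not in rep

    def test_unassigned_truth_code_rejected(self):
        spec = group_by_sample_size({"a": 1}, 1)
        with pytest.raises(KeyError):
            per_group_report([["z"]], ["z"], spec, 1)


class TestEvalReport:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            EvalReport(top1=0.9, top3=0.8, top1_ci=(0.8, 1.0),
                       top3_ci=(0.7, 0.9), n=10)
        with pytest.raises(ValueError):
            EvalReport(top1=0.5, top3=0.9, top1_ci=(0.6, 0.7),
                       top3_ci=(0.8, 1.0), n=10)

    def test_full_report_assembly(self):
        preds = [["a", "b", "c"]] * 10 + [["b", "a", "c"]] * 10
        truth = ["a"] * 20
        rep = evaluate_predictions(preds, truth, reps=100, seed=0,
                                   hypotheses=["a b"] * 20,
                                   references=["a b"] * 20)
        assert rep.top1 == 0.5 and rep.top3 == 1.0
        assert rep.bleu == pytest.approx(1.0)
        assert rep.as_dict()["n"] == 20
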